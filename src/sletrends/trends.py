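"""Trend estimation: logistic any-use models, Wilcoxon rank-sum tests and
quantile regression of cumulative exposure over a percentile grid with a
person-level bootstrap.

The quantile-regression estimator minimises the check loss
``sum rho_tau(y - X beta)`` with ``rho_tau(u) = u * (tau - 1{u < 0})`` via
its linear-programming dual, solved with HiGHS. Ties among minimisers are
resolved deterministically by evaluating at ``tau - 1e-6``: the solution
path beta(tau) is piecewise constant in tau, so this returns the left
limit, which for an intercept-only design is the lowest minimiser (the
inverted-CDF sample quantile).

Confidence intervals for quantile models come from a nonparametric
percentile bootstrap over persons (rows), reported together with the
bootstrap standard error. Logistic models report Wald intervals and
p-values. The Wilcoxon test uses midranks, exact enumeration of the
rank-sum null distribution when that is computationally feasible, and a
tie-corrected, continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.optimize import linprog

DEFAULT_TAU_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.901, 0.05), 2))

#: 5-year analyses use persons diagnosed up to this date (the last cohort
#: is not fully enrolled for year-5 outcomes).
YEAR5_MAX_DIAGNOSIS = pd.Timestamp("2016-12-31")

_EXACT_ENUM_LIMIT = 200_000  # max number of splits enumerated exactly


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

class WilcoxonResult(NamedTuple):
    statistic: float  # rank sum of x, midranks
    pvalue: float
    method: str


def wilcoxon_rank_sum(x, y, method: str = "auto") -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    Exact: the null distribution of the rank-sum is enumerated over all
    assignments of the pooled values to the two groups whenever the number
    of splits is at most 200,000 (covers any pooled n <= 20 with a group
    of at most 10, and all splits with pooled n <= 12). Otherwise a normal
    approximation with tie-corrected variance and continuity correction.
    ``method`` forces one of ``{"exact", "asymptotic"}``.
    """
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[:n].sum())

    feasible = comb(n + m, min(n, m)) <= _EXACT_ENUM_LIMIT
    if method == "exact" and not feasible:
        raise ValueError("exact enumeration infeasible for these sample sizes")
    if (method in ("auto", "exact")) and feasible:
        small = min(n, m)
        idx = np.fromiter(
            itertools.chain.from_iterable(
                itertools.combinations(range(n + m), small)),
            dtype=np.intp).reshape(-1, small)
        dist = ranks[idx].sum(axis=1)
        if small != n:  # enumerated the y-side; transform to x rank sums
            dist = ranks.sum() - dist
        eps = 1e-9
        p_low = np.mean(dist <= w + eps)
        p_high = np.mean(dist >= w - eps)
        p = min(1.0, 2.0 * min(p_low, p_high))
        return WilcoxonResult(w, float(p), "exact")

    mu = n * (n + m + 1) / 2.0
    nn = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = n * m / 12.0 * (nn + 1 - tie_term / (nn * (nn - 1)))
    if var <= 0:
        return WilcoxonResult(w, 1.0, "asymptotic")
    diff = w - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(w, float(p), "asymptotic")


# ---------------------------------------------------------------------------
# quantile regression

def fit_quantreg(X, y, tau: float, tie_shift: float = 1e-6,
                 solver: str = "lp") -> np.ndarray:
    """Check-loss minimising coefficients at quantile ``tau``.

    ``solver='lp'`` (default) solves the LP dual exactly: maximise y'a
    subject to X'a = (1 - tau) X'1 and 0 <= a <= 1; the equality
    multipliers are the primal coefficients, and ``tie_shift`` implements
    the left-limit tie rule (see module notes). ``solver='irls'`` is a
    fast iteratively-reweighted-least-squares approximation of the same
    minimiser (agreement typically ~1e-5 relative); it is used for
    bootstrap resampling where thousands of refits are needed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    n, p = X.shape
    # rank via the Gram matrix: cheap for tall-skinny dummy designs
    if n < p or np.linalg.matrix_rank(X.T @ X) < p:
        raise ValueError("design matrix is rank deficient on the estimation subset")
    if solver not in ("lp", "irls"):
        raise ValueError(f"unknown solver {solver!r}")
    sat = _saturated_cells(X, p)
    if sat is not None:
        # saturated design (p distinct rows): the check loss separates by
        # cell, so per-cell inverted-CDF quantiles are the exact minimiser
        # under the same left-limit tie rule; no LP needed
        uniq, cell = sat
        cell_q = np.array([
            np.quantile(y[cell == j], tau, method="inverted_cdf")
            for j in range(p)
        ])
        return np.linalg.solve(uniq, cell_q)
    if solver == "irls":
        return _quantreg_irls(X, y, tau)
    t = tau - tie_shift
    res = linprog(
        c=-y,
        A_eq=sparse.csr_matrix(X.T),
        b_eq=(1.0 - t) * X.sum(axis=0),
        bounds=(0.0, 1.0),
        method="highs",
        options={"presolve": False},
    )
    if not res.success:
        raise RuntimeError(f"quantile regression LP failed: {res.message}")
    beta = np.asarray(res.eqlin.marginals, dtype=float)
    # sign convention: marginals of the maximisation written as a minimisation
    loss_pos = _check_loss(y - X @ beta, tau)
    loss_neg = _check_loss(y + X @ beta, tau)
    return beta if loss_pos <= loss_neg else -beta


def _saturated_cells(X: np.ndarray, p: int):
    """If X has exactly p distinct rows, return (distinct rows, cell index
    per observation); otherwise None. Lexsort-based, exact comparison."""
    order = np.lexsort(X.T)
    Xs = X[order]
    new = np.empty(len(X), dtype=bool)
    new[0] = True
    np.any(Xs[1:] != Xs[:-1], axis=1, out=new[1:])
    if int(new.sum()) != p:
        return None
    cell_sorted = np.cumsum(new) - 1
    cell = np.empty(len(X), dtype=np.intp)
    cell[order] = cell_sorted
    return Xs[new], cell


def _quantreg_irls(X, y, tau, max_iter=60, rtol=1e-9):
    """Schlossmacher-style IRLS for the check loss, residuals floored to
    keep weights finite; deterministic and solver-free."""
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    scale = float(np.mean(np.abs(y - np.median(y)))) or 1.0
    floor = 1e-8 * scale
    for _ in range(max_iter):
        r = y - X @ beta
        w = np.where(r >= 0, tau, 1.0 - tau) / np.maximum(np.abs(r), floor)
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        if np.max(np.abs(beta_new - beta)) < rtol * scale:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _check_loss(u: np.ndarray, tau: float) -> float:
    return float(np.sum(u * (tau - (u < 0))))


# ---------------------------------------------------------------------------
# model designs

@dataclass
class ModelDesign:
    """Outcome, categorical covariates (first level = reference) and the
    estimation-subset rule for a trend model."""

    outcome: str
    factors: dict[str, Sequence[str]] = field(default_factory=dict)
    subset: Callable[[pd.DataFrame], pd.Series] | None = None

    def estimation_frame(self, data: pd.DataFrame) -> pd.DataFrame:
        df = data
        if self.subset is not None:
            df = df[self.subset(df)]
        return df.reset_index(drop=True)

    def design_matrix(self, df: pd.DataFrame):
        cols = [np.ones(len(df))]
        names = ["intercept"]
        for col, levels in self.factors.items():
            levels = list(levels)
            observed = set(df[col].dropna().unique())
            unknown = observed - set(levels)
            if unknown:
                raise ValueError(f"unexpected level(s) {sorted(unknown)} in {col!r}")
            for level in levels[1:]:  # first level is the reference
                if level in observed:
                    cols.append((df[col] == level).to_numpy(dtype=float))
                    names.append(f"{col}[{level}]")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"design matrix is not full rank; check factors {list(self.factors)}")
        return X, names


def adjusted_factors(cohorts: Sequence[str] = ("2005-2008", "2009-2012",
                                               "2013-2016", "2017-2021")):
    """The standard adjustment set: calendar cohort plus patient
    characteristics, with the published reference levels."""
    return {
        "calendar_cohort": list(cohorts),
        "age_category": ["18-39", "40-59", ">=60"],
        "sex": ["female", "male"],
        "education": ["0-9y", "10-12y", ">=13y", "missing"],
        "birth_region": ["Nordic", "non-Nordic", "missing"],
        "diagnosis_hospital": ["other", "university"],
        "prior_hospital_days_cat": ["0", "1-7", ">7"],
        "prior_outpatient_visits_cat": ["0-2", "3-6", ">6"],
    }


# ---------------------------------------------------------------------------
# logistic any-use models

def fit_logistic_anyuse(data: pd.DataFrame, design: ModelDesign,
                        ci_level: float = 0.95) -> pd.DataFrame:
    """Adjusted odds ratios per factor level vs its reference.

    Maximum-likelihood logistic fit; returns one row per non-intercept
    term with the log-odds-ratio estimate, Wald standard error, OR with
    Wald CI and p-value.
    """
    import statsmodels.api as sm

    df = design.estimation_frame(data)
    y = df[design.outcome].astype(float).to_numpy()
    if len(df) == 0:
        raise ValueError("empty estimation subset")
    if y.min() == y.max():
        raise ValueError(f"outcome {design.outcome!r} has no variation "
                         "(no events or all events)")
    X, names = design.design_matrix(df)
    model = sm.Logit(y, X)
    try:
        fit = model.fit(disp=0, maxiter=200)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular design in logistic model: {err}") from err
    if not fit.mle_retvals.get("converged", True):
        raise ValueError("logistic model failed to converge "
                         "(possible separation); inspect the design")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    out = pd.DataFrame({
        "model": "logistic",
        "outcome": design.outcome,
        "term": names,
        "estimate": fit.params,        # log odds ratio
        "se": fit.bse,
        "or": np.exp(fit.params),
        "or_ci_low": np.exp(fit.params - z * fit.bse),
        "or_ci_high": np.exp(fit.params + z * fit.bse),
        "p_value": fit.pvalues,
        "ci_level": ci_level,
        "n": len(df),
    })
    return out[out["term"] != "intercept"].reset_index(drop=True)


# ---------------------------------------------------------------------------
# quantile-regression trend models

def fit_quantile_regression(data: pd.DataFrame, design: ModelDesign,
                            tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
                            solver: str = "lp") -> pd.DataFrame:
    """Quantile-regression coefficients at every tau in the grid."""
    df = design.estimation_frame(data)
    if len(df) == 0:
        raise ValueError("empty estimation subset")
    y = df[design.outcome].astype(float).to_numpy()
    X, names = design.design_matrix(df)
    rows = []
    for tau in tau_grid:
        beta = fit_quantreg(X, y, float(tau), solver=solver)
        for name, b in zip(names, beta):
            rows.append((float(tau), name, b))
    out = pd.DataFrame(rows, columns=["tau", "term", "estimate"])
    out.insert(0, "outcome", design.outcome)
    out.insert(0, "model", "quantile")
    out["n"] = len(df)
    return out


def bootstrap_ci(fit: Callable[[pd.DataFrame], pd.Series], data: pd.DataFrame,
                 n_boot: int = 500, level: float = 0.90,
                 seed: int | None = None,
                 max_dropped_frac: float = 0.10,
                 point: pd.Series | None = None) -> pd.DataFrame:
    """Percentile bootstrap over persons (rows) for an arbitrary fitter.

    ``fit`` maps a data frame to a Series of estimates (any index). The
    full-data estimate is returned with percentile CIs and the bootstrap
    standard error. Replicates whose fit degenerates (rank-deficient or
    empty subset) are dropped and counted; more than 10% dropped is an
    error.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if point is None:
        point = fit(data)
    rng = np.random.default_rng(seed)
    n = len(data)
    reps, dropped = [], 0
    for _ in range(n_boot):
        take = rng.integers(0, n, n)
        try:
            reps.append(fit(data.iloc[take]))
        except (ValueError, np.linalg.LinAlgError):
            dropped += 1
    if dropped > max_dropped_frac * n_boot:
        raise RuntimeError(
            f"{dropped}/{n_boot} bootstrap replicates degenerate; "
            "the design is too fragile for resampling")
    mat = pd.concat(reps, axis=1)
    alpha = (1.0 - level) / 2.0
    out = pd.DataFrame({
        "estimate": point,
        "se": mat.std(axis=1, ddof=1),
        "ci_low": mat.quantile(alpha, axis=1),
        "ci_high": mat.quantile(1.0 - alpha, axis=1),
    })
    out["ci_level"] = level
    out["n_boot"] = n_boot - dropped
    return out


def fit_quantile_trend(data: pd.DataFrame, design: ModelDesign,
                       tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
                       n_boot: int = 500, level: float = 0.90,
                       seed: int | None = None,
                       boot_solver: str = "irls") -> pd.DataFrame:
    """Quantile regression across the tau grid with bootstrap CIs.

    The point estimate uses the exact LP solver; bootstrap replicates use
    the fast IRLS approximation by default (``boot_solver='lp'`` forces
    exact refits). Returns tidy rows (model, outcome, tau, term,
    estimate, se, ci_low, ci_high, ci_level, n, n_boot); the
    calendar-cohort terms are the quantile shifts attributable to
    diagnosis period.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    df = design.estimation_frame(data)
    if len(df) == 0:
        raise ValueError("empty estimation subset")
    y = df[design.outcome].astype(float).to_numpy()
    X, names = design.design_matrix(df)
    taus = [float(t) for t in tau_grid]
    point = np.array([fit_quantreg(X, y, t, solver="lp") for t in taus])

    rng = np.random.default_rng(seed)
    n = len(y)
    reps = np.full((n_boot, len(taus), X.shape[1]), np.nan)
    dropped = 0
    for b in range(n_boot):
        take = rng.integers(0, n, n)
        Xb, yb = X[take], y[take]
        try:
            for i, t in enumerate(taus):
                reps[b, i] = fit_quantreg(Xb, yb, t, solver=boot_solver)
        except (ValueError, np.linalg.LinAlgError):
            reps[b] = np.nan
            dropped += 1
    if dropped > 0.10 * n_boot:
        raise RuntimeError(
            f"{dropped}/{n_boot} bootstrap replicates degenerate; "
            "the design is too fragile for resampling")
    alpha = (1.0 - level) / 2.0
    rows = []
    for i, t in enumerate(taus):
        for j, name in enumerate(names):
            draw = reps[:, i, j]
            draw = draw[~np.isnan(draw)]
            rows.append({
                "model": "quantile", "outcome": design.outcome,
                "tau": t, "term": name, "estimate": point[i, j],
                "se": float(np.std(draw, ddof=1)),
                "ci_low": float(np.quantile(draw, alpha)),
                "ci_high": float(np.quantile(draw, 1.0 - alpha)),
                "ci_level": level, "n": n, "n_boot": int(len(draw)),
            })
    return pd.DataFrame(rows)
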