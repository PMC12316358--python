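"""Table-shaped data products: baseline characteristics, any-use trends
with odds ratios, yearly state-transition (alluvial) tables and the
GC-dose x HCQ-PDC cross-tabulation with a chi-square independence summary.

Percentages are count/denominator x 100 rounded half-up to one decimal,
matching how registry tables are conventionally printed.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import GC_DOSE_CATEGORIES, HCQ_PDC_CATEGORIES
from .trends import YEAR5_MAX_DIAGNOSIS

CENSORED_STATE = "censored"


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, denominator: float, ndigits: int = 1) -> float:
    """Printed percentage: 100 * count / denominator, rounded half-up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * count / denominator, ndigits)


_CHARACTERISTIC_VARS = {
    "sex": ["female", "male"],
    "age_category": ["18-39", "40-59", ">=60"],
    "birth_region": ["Nordic", "non-Nordic", "missing"],
    "diagnosis_hospital": ["university", "other"],
    "education": ["0-9y", "10-12y", ">=13y", "missing"],
    "prior_hospital_days_cat": ["0", "1-7", ">7"],
    "prior_outpatient_visits_cat": ["0-2", "3-6", ">6"],
}


def table_characteristics(cohort: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics by calendar cohort and overall.

    Tidy rows: (variable, level, stratum, n, count, pct) for categorical
    variables plus continuous age rows (mean, sd, median, min, max).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    strata = [(label, cohort[cohort["calendar_cohort"] == label])
              for label in sorted(cohort["calendar_cohort"].dropna().unique())]
    strata.append(("total", cohort))
    rows = []
    for label, df in strata:
        denom = len(df)
        if denom == 0:
            continue
        age = df["age_at_diagnosis"]
        rows += [
            ("age_years", "mean", label, denom, float(age.mean()), np.nan),
            ("age_years", "sd", label, denom, float(age.std(ddof=1)) if denom > 1 else 0.0, np.nan),
            ("age_years", "median", label, denom, float(age.median()), np.nan),
            ("age_years", "min", label, denom, float(age.min()), np.nan),
            ("age_years", "max", label, denom, float(age.max()), np.nan),
        ]
        for var, levels in _CHARACTERISTIC_VARS.items():
            if var not in df.columns:
                continue
            for level in levels:
                count = int((df[var] == level).sum())
                rows.append((var, level, label, denom, count,
                             percentage(count, denom)))
    return pd.DataFrame(
        rows, columns=["variable", "level", "stratum", "n", "count", "pct"])


def table_anyuse_trend(cohort: pd.DataFrame, exposures: pd.DataFrame,
                       estimates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Any-use of GC and HCQ in years 1 and 5 by calendar cohort.

    Year-1 rows use everyone (the cohort requires >= 1 year follow-up);
    year-5 rows are restricted to persons with >= 5 years of follow-up
    and diagnosis by 2016 (the last cohort is not fully enrolled, so it
    is absent from the year-5 block). Odds-ratio columns are joined from
    a logistic-estimates frame when given.
    """
    frames = []
    for year, window in ((1, "year1"), (5, "year5")):
        sub = cohort
        if year == 5:
            sub = cohort[(cohort["follow_up_years"] >= 5.0)
                         & (cohort["diagnosis_date"] <= YEAR5_MAX_DIAGNOSIS)]
        exp = exposures[exposures["window"] == window].merge(
            sub[["person_id", "calendar_cohort"]], on="person_id", how="inner")
        for drug, col in (("GC", "any_gc"), ("HCQ", "any_hcq")):
            g = exp.groupby("calendar_cohort")[col].agg(["sum", "size"])
            for cohort_label, row in g.iterrows():
                users, denom = int(row["sum"]), int(row["size"])
                frames.append({
                    "year": year, "drug": drug, "calendar_cohort": cohort_label,
                    "n": denom, "n_users": users,
                    "pct": percentage(users, denom) if denom else np.nan,
                })
    out = pd.DataFrame(frames)
    if estimates is not None:
        est = estimates.copy()
        est["calendar_cohort"] = (est["term"].str.extract(
            r"calendar_cohort\[(.+)\]")[0])
        est = est.dropna(subset=["calendar_cohort"])
        out = out.merge(
            est[["year", "drug", "calendar_cohort", "or", "or_ci_low",
                 "or_ci_high", "p_value"]],
            on=["year", "drug", "calendar_cohort"], how="left")
    return out


def transition_tables(exposures: pd.DataFrame, cohort: pd.DataFrame,
                      k_max: int = 5) -> pd.DataFrame:
    """Year-to-year exposure-state transitions (alluvial-plot tables).

    For each drug (GC daily-dose category; HCQ PDC category), calendar
    cohort and year k -> k+1: counts of persons moving between states.
    Persons observed in year k but censored before year k+1 flow to an
    explicit "censored" state, so every table conserves persons.
    """
    state_cols = {"GC": "gc_dose_category", "HCQ": "hcq_pdc_category"}
    exp = exposures.merge(cohort[["person_id", "calendar_cohort"]],
                          on="person_id", how="inner")
    rows = []
    for drug, col in state_cols.items():
        wide = exp.pivot(index=["person_id", "calendar_cohort"],
                         columns="window", values=col)
        for k in range(1, k_max):
            a, b = f"year{k}", f"year{k + 1}"
            if a not in wide.columns:
                continue
            sub = wide[wide[a].notna()]
            to_state = (sub[b] if b in sub.columns
                        else pd.Series(np.nan, index=sub.index))
            to_state = to_state.fillna(CENSORED_STATE)
            g = (pd.DataFrame({
                "calendar_cohort": sub.index.get_level_values("calendar_cohort"),
                "from_state": sub[a].to_numpy(),
                "to_state": to_state.to_numpy()})
                .groupby(["calendar_cohort", "from_state", "to_state"])
                .size().rename("count").reset_index())
            g.insert(0, "to_year", k + 1)
            g.insert(0, "from_year", k)
            g.insert(0, "drug", drug)
            rows.append(g)
    out = pd.concat(rows, ignore_index=True)
    totals = out.groupby(["drug", "from_year", "calendar_cohort", "from_state"]
                         )["count"].transform("sum")
    out["proportion"] = out["count"] / totals
    return out


def crosstab_gc_hcq(exposures: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """5-year GC average-daily-dose category x HCQ PDC category, per
    calendar cohort, with a chi-square independence statistic.

    Tidy counts with the chi-square statistic/p attached per stratum;
    strata where the test is undefined (fewer than two occupied rows or
    columns) carry NaN statistics.
    """
    exp = exposures[exposures["window"] == "cum"].merge(
        cohort[["person_id", "calendar_cohort"]], on="person_id", how="inner")
    rows = []
    for label, df in exp.groupby("calendar_cohort"):
        tab = pd.crosstab(df["gc_dose_category"], df["hcq_pdc_category"])
        tab = tab.reindex(index=[c for c in GC_DOSE_CATEGORIES if c in tab.index],
                          columns=[c for c in HCQ_PDC_CATEGORIES if c in tab.columns])
        occupied = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
        if occupied.shape[0] >= 2 and occupied.shape[1] >= 2:
            chi2, p, dof, _ = stats.chi2_contingency(occupied)
        else:
            chi2, p, dof = np.nan, np.nan, 0
        long = tab.stack().rename("count").reset_index()
        long.insert(0, "calendar_cohort", label)
        long["chi2"] = chi2
        long["chi2_p"] = p
        long["chi2_dof"] = dof
        rows.append(long)
    return pd.concat(rows, ignore_index=True)
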