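"""Dispensation-based drug-exposure measures.

Converts pharmacy-fill streams into the analysis exposures:

* yearly any-use flags (at least one dispensation of the class in the
  365.25-day window, half-open, counted from diagnosis);
* cumulative prednisolone-equivalent glucocorticoid dose, from the number
  of dispensed DDDs times the substance's DDD size and potency factor,
  each fill attributed wholly to the window containing its fill date;
* hydroxychloroquine coverage intervals: a 1-package dispensation covers
  100 days, a multi-package dispensation 75 days per package; when a new
  fill arrives inside the current coverage the prior supply is treated as
  fully consumed (no stockpiling) and coverage continues from the new
  fill; coverage is truncated at end of follow-up;
* proportion of days covered (PDC): covered days divided by follow-up
  days in the window of interest;
* average-daily-dose categories {none, (0,5], (5,7.5], >7.5} mg/day and
  the eight-way treatment-combination state.

Dispensations dated before diagnosis are excluded from every window; a
classic stockpiling policy (carry leftover supply forward) is available
behind ``stockpiling=True`` for sensitivity analyses only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .codes import ATC_CLASSES, DEFAULT_EQUIVALENCE, EquivalenceTable

DAYS_PER_YEAR = 365.25
SINGLE_PACKAGE_DAYS = 100.0  # days covered by a one-package HCQ dispensation
MULTI_PACKAGE_DAYS = 75.0    # days covered per package when >1 package at once

GC_DOSE_CATEGORIES = ["none", "(0,5]", "(5,7.5]", ">7.5"]
HCQ_PDC_CATEGORIES = ["0", "(0,0.2]", "(0.2,0.8]", ">0.8"]


def yearly_windows(diagnosis_date, follow_up_end, k_max: int):
    """Half-open yearly windows ``[dx+(k-1)*365.25, dx+k*365.25)`` truncated
    at ``follow_up_end``; zero-length windows are omitted."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    dx = pd.Timestamp(diagnosis_date)
    end = pd.Timestamp(follow_up_end)
    if end <= dx:
        raise ValueError("follow_up_end must be after diagnosis_date")
    out = []
    for k in range(1, k_max + 1):
        lo = dx + pd.Timedelta(days=(k - 1) * DAYS_PER_YEAR)
        hi = min(dx + pd.Timedelta(days=k * DAYS_PER_YEAR), end)
        if hi > lo:
            out.append((lo, hi))
    return out


def gc_cumulative_dose(dispensations: pd.DataFrame,
                       equivalence: EquivalenceTable = DEFAULT_EQUIVALENCE,
                       window=None) -> float:
    """Prednisolone-equivalent mg: sum of n_ddd x ddd_mg x potency factor.

    ``window`` is an optional (start, end) pair; fills are attributed to
    the window containing their fill date (half-open).
    """
    df = dispensations
    if window is not None:
        lo, hi = window
        df = df[(df["fill_date"] >= lo) & (df["fill_date"] < hi)]
    if df.empty:
        return 0.0
    per_ddd = df["atc_code"].map(equivalence.mg_per_ddd)
    return float((df["n_ddd"] * per_ddd).sum())


def _merge_same_day(disp: pd.DataFrame) -> pd.DataFrame:
    """Same-day fills merged into one dispensation event, packages summed."""
    return (disp.groupby(["person_id", "fill_date"], as_index=False, sort=True)
            ["n_packages"].sum())


def nominal_duration(n_packages) -> np.ndarray:
    """Days covered by one dispensation event: 100 for a single package,
    75 per package otherwise."""
    n = np.asarray(n_packages)
    return np.where(n == 1, SINGLE_PACKAGE_DAYS, MULTI_PACKAGE_DAYS * n)


def hcq_coverage_intervals(dispensations: pd.DataFrame, follow_up_end=None,
                           stockpiling: bool = False) -> pd.DataFrame:
    """Coverage intervals ``[start, end)`` from HCQ dispensations.

    ``follow_up_end`` may be a single date or a per-person mapping
    (``person_id -> date``). Fills after follow-up end are dropped with a
    warning. Output intervals are disjoint and chronologically ordered
    within person. Under the default no-stockpiling rule each interval
    ends at the next fill if that comes before the nominal supply runs
    out; with ``stockpiling=True`` leftover days are carried forward.
    """
    if dispensations.empty:
        return pd.DataFrame({"person_id": pd.Series(dtype=object),
                             "start": pd.Series(dtype="datetime64[ns]"),
                             "end": pd.Series(dtype="datetime64[ns]"),
                             "days": pd.Series(dtype=float)})
    disp = _merge_same_day(dispensations)

    if follow_up_end is None:
        fue = pd.Series(pd.Timestamp.max.floor("D"), index=disp.index)
    elif np.isscalar(follow_up_end) or isinstance(
            follow_up_end, (pd.Timestamp, np.datetime64)) or hasattr(
            follow_up_end, "toordinal"):
        fue = pd.Series(pd.Timestamp(follow_up_end), index=disp.index)
    else:
        fue = disp["person_id"].map(pd.Series(follow_up_end))
        if fue.isna().any():
            missing = disp.loc[fue.isna(), "person_id"].unique()
            raise ValueError(f"no follow-up end for persons {list(missing)[:5]}")

    late = disp["fill_date"] >= fue
    if late.any():
        warnings.warn(f"dropping {int(late.sum())} dispensations after "
                      "end of follow-up", stacklevel=2)
        disp, fue = disp[~late], fue[~late]
    if disp.empty:
        return hcq_coverage_intervals(dispensations.iloc[0:0])

    dur = nominal_duration(disp["n_packages"])
    if stockpiling:
        frames = []
        for pid, grp in disp.groupby("person_id", sort=True):
            end_limit = fue[grp.index[0]]
            supply_end = None
            for fill, d in zip(grp["fill_date"], nominal_duration(grp["n_packages"])):
                start = fill if supply_end is None else max(fill, supply_end)
                supply_end = start + pd.Timedelta(days=float(d))
                frames.append((pid, start, min(supply_end, end_limit)))
        out = pd.DataFrame(frames, columns=["person_id", "start", "end"])
    else:
        next_fill = disp.groupby("person_id")["fill_date"].shift(-1)
        end = disp["fill_date"] + pd.to_timedelta(dur, unit="D")
        end = end.where(next_fill.isna() | (next_fill > end), next_fill)
        end = end.clip(upper=fue)
        out = pd.DataFrame({"person_id": disp["person_id"].to_numpy(),
                            "start": disp["fill_date"].to_numpy(),
                            "end": end.to_numpy()})
    out = out[out["end"] > out["start"]].reset_index(drop=True)
    out["days"] = (out["end"] - out["start"]) / pd.Timedelta(days=1)
    return out


def pdc(intervals: pd.DataFrame, window) -> float:
    """Proportion of days covered: overlap of the coverage intervals with
    the window, divided by the window length. The window must already be
    truncated at end of follow-up."""
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    total = (hi - lo) / pd.Timedelta(days=1)
    if total <= 0:
        raise ValueError("zero-length window")
    if intervals.empty:
        return 0.0
    start = intervals["start"].clip(lower=lo)
    end = intervals["end"].clip(upper=hi)
    covered = ((end - start) / pd.Timedelta(days=1)).clip(lower=0).sum()
    return float(covered / total)


def any_use_flags(dispensations: pd.DataFrame, window,
                  atc_classes: dict[str, str] = ATC_CLASSES) -> dict[str, bool]:
    """Any-use booleans per drug class within the half-open window;
    the seven immunosuppressant subclasses pool into ``any_is``."""
    lo, hi = window
    in_win = dispensations[(dispensations["fill_date"] >= lo)
                           & (dispensations["fill_date"] < hi)]
    classes = set(in_win["atc_code"].map(atc_classes).dropna())
    return {
        "any_gc": "GC" in classes,
        "any_hcq": "HCQ" in classes,
        "any_is": any(c.startswith("IS:") for c in classes),
    }


def combination_state(any_gc: bool, any_hcq: bool, any_is: bool) -> str:
    """Eight-way treatment combination label."""
    parts = [name for flag, name in
             ((any_is, "IS"), (any_hcq, "HCQ"), (any_gc, "GC")) if flag]
    return "+".join(parts) if parts else "None"


def avg_daily_dose_category(gc_cum_dose_mg: float, window_days: float) -> str:
    """Average daily GC dose category: none / (0,5] / (5,7.5] / >7.5 mg/day."""
    if window_days <= 0:
        raise ValueError("window_days must be > 0")
    daily = gc_cum_dose_mg / window_days
    if daily <= 0:
        return "none"
    if daily <= 5:
        return "(0,5]"
    if daily <= 7.5:
        return "(5,7.5]"
    return ">7.5"


def pdc_category(value: float) -> str:
    """HCQ PDC bins 0 / (0,0.2] / (0.2,0.8] / >0.8."""
    if value <= 0:
        return "0"
    if value <= 0.2:
        return "(0,0.2]"
    if value <= 0.8:
        return "(0.2,0.8]"
    return ">0.8"


# ---------------------------------------------------------------------------
# batch summary

def summarize_exposures(cohort: pd.DataFrame, dispensations: pd.DataFrame,
                        equivalence: EquivalenceTable = DEFAULT_EQUIVALENCE,
                        atc_classes: dict[str, str] = ATC_CLASSES,
                        k_max: int = 5) -> pd.DataFrame:
    """Windowed exposure summary, one row per person and window.

    Windows are ``year1`` .. ``year{k_max}`` plus the pooled ``5yr``-style
    window (labelled ``cum``) spanning ``[diagnosis, diagnosis +
    k_max*365.25)``; all truncated at the person's follow-up end, with
    empty windows omitted. Columns follow the per-window operations:
    any-use flags, GC cumulative dose and daily-dose category, HCQ covered
    days and PDC, and the combination state.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    need = {"person_id", "diagnosis_date", "follow_up_end"}
    if not need.issubset(cohort.columns):
        raise ValueError(f"cohort lacks columns {sorted(need - set(cohort.columns))}")

    base = cohort[["person_id", "diagnosis_date", "follow_up_end"]].copy()
    d = dispensations.merge(base, on="person_id", how="inner")
    d = d[(d["fill_date"] >= d["diagnosis_date"])
          & (d["fill_date"] < d["follow_up_end"])].copy()
    d["offset"] = (d["fill_date"] - d["diagnosis_date"]).dt.days.astype(float)
    d["widx"] = np.floor(d["offset"] / DAYS_PER_YEAR).astype(int) + 1
    d = d[d["widx"] <= k_max]
    d["drug"] = d["atc_code"].map(atc_classes)
    d.loc[d["drug"].str.startswith("IS:", na=False), "drug"] = "IS"

    fu_days = ((base["follow_up_end"] - base["diagnosis_date"])
               .dt.days.astype(float).to_numpy())

    # window lengths per person x year (truncated, zero-length omitted later)
    k = np.arange(1, k_max + 1)
    win_lo = (k - 1) * DAYS_PER_YEAR
    win_hi = np.minimum(k * DAYS_PER_YEAR, fu_days[:, None])
    win_len = np.maximum(win_hi - win_lo, 0.0)

    npers = len(base)
    pid_order = pd.Index(base["person_id"])

    def _pivot(frame, values, aggfunc):
        if frame.empty:
            return np.zeros((npers, k_max))
        t = frame.pivot_table(index="person_id", columns="widx", values=values,
                              aggfunc=aggfunc, fill_value=0)
        t = t.reindex(index=pid_order, columns=k, fill_value=0)
        return t.to_numpy(dtype=float)

    gc = d[d["drug"] == "GC"].copy()
    if not gc.empty:
        gc["pe_mg"] = gc["n_ddd"] * gc["atc_code"].map(equivalence.mg_per_ddd)
        missing = gc["pe_mg"].isna()
        if missing.any():
            raise KeyError("GC ATC codes missing from equivalence table: "
                           f"{sorted(gc.loc[missing, 'atc_code'].unique())}")
    gc_dose = _pivot(gc, "pe_mg", "sum") if not gc.empty else np.zeros((npers, k_max))
    any_gc = _pivot(d[d["drug"] == "GC"], "offset", "count") > 0
    any_hcq = _pivot(d[d["drug"] == "HCQ"], "offset", "count") > 0
    any_is = _pivot(d[d["drug"] == "IS"], "offset", "count") > 0

    # HCQ covered days per window, from the vectorised interval construction
    hcq = d[d["drug"] == "HCQ"]
    fue_map = base.set_index("person_id")["follow_up_end"]
    intervals = hcq_coverage_intervals(hcq, fue_map) if not hcq.empty else None
    hcq_days = np.zeros((npers, k_max))
    if intervals is not None and not intervals.empty:
        iv = intervals.merge(base, on="person_id")
        s_off = (iv["start"] - iv["diagnosis_date"]).dt.days.astype(float).to_numpy()
        e_off = ((iv["end"] - iv["diagnosis_date"]) / pd.Timedelta(days=1)).to_numpy()
        row = pid_order.get_indexer(iv["person_id"])
        for kk in k:
            lo, hi = (kk - 1) * DAYS_PER_YEAR, kk * DAYS_PER_YEAR
            ol = np.clip(np.minimum(e_off, hi) - np.maximum(s_off, lo), 0, None)
            np.add.at(hcq_days, (row, np.full(len(row), kk - 1)), ol)

    rows = []
    labels = [f"year{kk}" for kk in k]
    for j, label in enumerate(labels):
        live = win_len[:, j] > 0
        rows.append(pd.DataFrame({
            "person_id": base["person_id"].to_numpy()[live],
            "window": label,
            "window_days": win_len[live, j],
            "any_gc": any_gc[live, j],
            "any_hcq": any_hcq[live, j],
            "any_is": any_is[live, j],
            "gc_cum_dose_mg": gc_dose[live, j],
            "hcq_days_covered": hcq_days[live, j],
        }))
    cum_len = win_len.sum(axis=1)
    live = cum_len > 0
    rows.append(pd.DataFrame({
        "person_id": base["person_id"].to_numpy()[live],
        "window": "cum",
        "window_days": cum_len[live],
        "any_gc": any_gc.any(axis=1)[live],
        "any_hcq": any_hcq.any(axis=1)[live],
        "any_is": any_is.any(axis=1)[live],
        "gc_cum_dose_mg": gc_dose.sum(axis=1)[live],
        "hcq_days_covered": hcq_days.sum(axis=1)[live],
    }))
    out = pd.concat(rows, ignore_index=True)
    out["gc_avg_daily_dose_mg"] = out["gc_cum_dose_mg"] / out["window_days"]
    out["hcq_pdc"] = np.clip(out["hcq_days_covered"] / out["window_days"], 0.0, 1.0)
    out["gc_dose_category"] = [
        avg_daily_dose_category(dose, days)
        for dose, days in zip(out["gc_cum_dose_mg"], out["window_days"])]
    out["hcq_pdc_category"] = out["hcq_pdc"].map(pdc_category)
    out["combination"] = [
        combination_state(g, h, i)
        for g, h, i in zip(out["any_gc"], out["any_hcq"], out["any_is"])]
    order = {label: j for j, label in enumerate(labels + ["cum"])}
    out["_o"] = out["window"].map(order)
    out = out.sort_values(["person_id", "_o"], kind="stable").drop(columns="_o")
    return out.reset_index(drop=True)
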