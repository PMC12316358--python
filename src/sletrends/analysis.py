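"""Pre-wired trend analyses mirroring the published modelling choices.

Each function joins the cohort covariates to the windowed exposures,
applies the published estimation-subset rules and fits the corresponding
model:

* ``anyuse_trends`` — logistic models of any GC / any HCQ use in year 1
  (everyone) and year 5 (>= 5 years follow-up, diagnosis by 2016),
  adjusted for the patient characteristics, odds ratios vs 2005-2008;
* ``gc_dose_trend`` — quantile regression of 5-year cumulative
  prednisolone-equivalent dose among persons with at least one GC
  dispensation in those 5 years, across the 10-90% percentile grid, with
  person-level bootstrap 90% CIs;
* ``hcq_pdc_trend`` — the same for the 5-year HCQ proportion of days
  covered among persons with at least one HCQ dispensation.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .trends import (
    DEFAULT_TAU_GRID,
    YEAR5_MAX_DIAGNOSIS,
    ModelDesign,
    adjusted_factors,
    fit_logistic_anyuse,
    fit_quantile_trend,
)


def _merge(cohort: pd.DataFrame, exposures: pd.DataFrame, window: str) -> pd.DataFrame:
    exp = exposures[exposures["window"] == window]
    return cohort.merge(exp, on="person_id", how="inner")


def _present_factors(df: pd.DataFrame, cohorts: Sequence[str] | None = None):
    factors = adjusted_factors()
    if cohorts is not None:
        factors["calendar_cohort"] = list(cohorts)
    return {col: levels for col, levels in factors.items() if col in df.columns}


def anyuse_trends(cohort: pd.DataFrame, exposures: pd.DataFrame,
                  adjusted: bool = True) -> pd.DataFrame:
    """Adjusted ORs for any GC/HCQ use in years 1 and 5 by calendar cohort."""
    rows = []
    for year, window in ((1, "year1"), (5, "year5")):
        sub = cohort
        if year == 5:
            sub = cohort[(cohort["follow_up_years"] >= 5.0)
                         & (cohort["diagnosis_date"] <= YEAR5_MAX_DIAGNOSIS)]
        df = _merge(sub, exposures, window)
        cohorts = sorted(df["calendar_cohort"].dropna().unique())
        factors = (_present_factors(df, cohorts) if adjusted
                   else {"calendar_cohort": cohorts})
        for drug, outcome in (("GC", "any_gc"), ("HCQ", "any_hcq")):
            est = fit_logistic_anyuse(df, ModelDesign(outcome, factors))
            est.insert(0, "drug", drug)
            est.insert(0, "year", year)
            rows.append(est)
    return pd.concat(rows, ignore_index=True)


def _five_year_subset(cohort: pd.DataFrame, exposures: pd.DataFrame,
                      use_flag: str) -> pd.DataFrame:
    df = _merge(cohort, exposures, "cum")
    return df[(df["follow_up_years"] >= 5.0)
              & (df["diagnosis_date"] <= YEAR5_MAX_DIAGNOSIS)
              & df[use_flag]].reset_index(drop=True)


def gc_dose_trend(cohort: pd.DataFrame, exposures: pd.DataFrame,
                  tau_grid=DEFAULT_TAU_GRID, n_boot: int = 500,
                  seed: int | None = 0, adjusted: bool = True) -> pd.DataFrame:
    """Quantile-regression trend in 5-year cumulative GC dose (mg)."""
    df = _five_year_subset(cohort, exposures, "any_gc")
    cohorts = sorted(df["calendar_cohort"].dropna().unique())
    factors = (_present_factors(df, cohorts) if adjusted
               else {"calendar_cohort": cohorts})
    design = ModelDesign("gc_cum_dose_mg", factors)
    return fit_quantile_trend(df, design, tau_grid, n_boot=n_boot, seed=seed)


def hcq_pdc_trend(cohort: pd.DataFrame, exposures: pd.DataFrame,
                  tau_grid=DEFAULT_TAU_GRID, n_boot: int = 500,
                  seed: int | None = 0, adjusted: bool = True) -> pd.DataFrame:
    """Quantile-regression trend in 5-year HCQ proportion of days covered."""
    df = _five_year_subset(cohort, exposures, "any_hcq")
    cohorts = sorted(df["calendar_cohort"].dropna().unique())
    factors = (_present_factors(df, cohorts) if adjusted
               else {"calendar_cohort": cohorts})
    design = ModelDesign("hcq_pdc", factors)
    return fit_quantile_trend(df, design, tau_grid, n_boot=n_boot, seed=seed)
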