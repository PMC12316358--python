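"""Simulation configuration.

``SimulationConfig`` holds every knob of the synthetic-register generator:
study window, calendar-cohort treatment effects (the ground truth that the
downstream pipeline is supposed to recover), demography, pre-diagnosis
healthcare utilization, drug-dispensation mechanics and censoring. Defaults
are calibrated to the published marginals of the Swedish incident-SLE
cohort this package emulates (82.5% female, mean age 48.8, 5-year
cumulative glucocorticoid dose medians 7500/7000/6500 mg by diagnosis
period, hydroxychloroquine initiation rising from ~45% to ~80%).
"""

from __future__ import annotations

import datetime as dt

from pydantic import BaseModel, Field, model_validator

from .codes import COHORT_PERIODS

Prob = Field(ge=0.0, le=1.0)


class CohortEffect(BaseModel):
    """True treatment parameters for one calendar cohort of diagnosis."""

    gc_median_5yr_dose_mg: float = Field(gt=0)
    gc_scale: float = Field(ge=0, description="lognormal sigma of the 5-yr GC dose")
    hcq_initiation_prob: float = Prob
    hcq_discontinuation_hazard: float = Field(ge=0, description="per year")
    is_use_prob: float = Prob


class Demography(BaseModel):
    female_prob: float = 0.825
    age_mean: float = 48.8
    age_sd: float = Field(default=18.1, gt=0)
    age_min: float = 18.0
    age_max: float = 97.0
    non_nordic_prob: float = 0.155
    missing_region_prob: float = 0.014
    education_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "0-9y": 0.220, "10-12y": 0.436, ">=13y": 0.337, "missing": 0.007,
        }
    )

    @model_validator(mode="after")
    def _check(self) -> "Demography":
        for name in ("female_prob", "non_nordic_prob", "missing_region_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        s = sum(self.education_probs.values())
        if abs(s - 1.0) > 1e-6 or min(self.education_probs.values()) < 0:
            raise ValueError("education_probs must be non-negative and sum to 1")
        if self.non_nordic_prob + self.missing_region_prob > 1.0:
            raise ValueError("region probabilities exceed 1")
        return self


class Utilization(BaseModel):
    """Pre-diagnosis healthcare use, correlated with latent severity."""

    severity_sigma: float = Field(default=0.6, gt=0)
    outpatient_mean: float = Field(default=3.8, ge=0)
    outpatient_dispersion: float = Field(default=1.4, gt=0)
    hospitalization_rate: float = Field(default=0.46, ge=0, description="stays/year")
    hospital_los_mean_days: float = Field(default=4.0, gt=0)
    sle_visit_rate: float = Field(default=0.6, ge=0, description="post-dx SLE visits/year")
    background_visit_rate: float = Field(default=0.4, ge=0, description="non-case visits/year")


class GCPattern(BaseModel):
    """Mechanics of the glucocorticoid dispensation stream."""

    user_prob: float = 0.87
    year1_start_prob: float = 0.80
    stop_prob: float = Field(default=0.13, gt=0, le=1.0,
                             description="per-year probability of stopping GC")
    taper: float = Field(default=0.6, gt=0, le=1.0,
                         description="geometric decay of yearly dose")
    fill_dose_mg: float = Field(default=1500.0, gt=0,
                                description="typical prednisolone-equivalent mg per fill")


class HCQPattern(BaseModel):
    """Mechanics of the hydroxychloroquine dispensation stream."""

    start_delay_max_days: float = Field(default=60.0, ge=0)
    refill_gap_days: tuple[float, float] = (80.0, 120.0)
    two_package_prob: float = 0.10

    @model_validator(mode="after")
    def _check(self) -> "HCQPattern":
        lo, hi = self.refill_gap_days
        if not 0 < lo <= hi:
            raise ValueError("refill_gap_days must satisfy 0 < low <= high")
        if not 0.0 <= self.two_package_prob <= 1.0:
            raise ValueError("two_package_prob must be a probability in [0, 1]")
        return self


class Censoring(BaseModel):
    """End of registration; death and emigration are exposed separately."""

    death_rate: float = Field(default=0.015, ge=0, description="per year")
    emigration_rate: float = Field(default=0.010, ge=0, description="per year")


def default_cohort_effects() -> dict[str, CohortEffect]:
    return {
        "2005-2008": CohortEffect(
            gc_median_5yr_dose_mg=7500, gc_scale=1.028,
            hcq_initiation_prob=0.45, hcq_discontinuation_hazard=0.285,
            is_use_prob=0.45),
        "2009-2012": CohortEffect(
            gc_median_5yr_dose_mg=7000, gc_scale=1.028,
            hcq_initiation_prob=0.64, hcq_discontinuation_hazard=0.21,
            is_use_prob=0.50),
        "2013-2016": CohortEffect(
            gc_median_5yr_dose_mg=6500, gc_scale=1.028,
            hcq_initiation_prob=0.73, hcq_discontinuation_hazard=0.18,
            is_use_prob=0.55),
        "2017-2021": CohortEffect(
            gc_median_5yr_dose_mg=6000, gc_scale=1.028,
            hcq_initiation_prob=0.80, hcq_discontinuation_hazard=0.12,
            is_use_prob=0.60),
    }


class SimulationConfig(BaseModel):
    """Full parameterisation of one synthetic register draw."""

    n_persons: int = Field(ge=1)
    seed: int = 0
    study_start: dt.date = dt.date(2005, 7, 1)
    study_end: dt.date = dt.date(2021, 9, 1)
    data_end: dt.date = dt.date(2024, 1, 31)

    cohort_effects: dict[str, CohortEffect] = Field(default_factory=default_cohort_effects)
    demography: Demography = Field(default_factory=Demography)
    utilization: Utilization = Field(default_factory=Utilization)
    gc: GCPattern = Field(default_factory=GCPattern)
    hcq: HCQPattern = Field(default_factory=HCQPattern)
    censoring: Censoring = Field(default_factory=Censoring)

    case_fraction: float = Prob
    prevalent_fraction: float = Prob
    underage_fraction: float = Prob
    recent_immigrant_fraction: float = Prob
    single_visit_fraction: float = Prob
    no_specialist_fraction: float = Prob

    def __init__(self, **data):  # defaults for the Prob-annotated fields
        data.setdefault("case_fraction", 0.90)
        data.setdefault("prevalent_fraction", 0.05)
        data.setdefault("underage_fraction", 0.02)
        data.setdefault("recent_immigrant_fraction", 0.02)
        data.setdefault("single_visit_fraction", 0.03)
        data.setdefault("no_specialist_fraction", 0.02)
        super().__init__(**data)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if not self.study_start < self.study_end < self.data_end:
            raise ValueError("require study_start < study_end < data_end")
        frac = (self.prevalent_fraction + self.underage_fraction
                + self.recent_immigrant_fraction + self.single_visit_fraction
                + self.no_specialist_fraction)
        if frac > 1.0:
            raise ValueError("injected case-violation fractions sum to more than 1")
        for label in self.cohort_effects:
            if label not in COHORT_PERIODS:
                raise ValueError(
                    f"unknown calendar cohort label {label!r}; "
                    f"expected one of {sorted(COHORT_PERIODS)}"
                )
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
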