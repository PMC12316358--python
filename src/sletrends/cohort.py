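"""Incident-SLE cohort construction from register tables.

Case definition: at least two SLE-coded visits (ICD-10 M32.1/M32.8/M32.9)
within 365 days, with at least one of the person's SLE-coded visits at a
specialist department; the candidate diagnosis date is the person's first
SLE-coded visit ever. Incidence filters, applied in a fixed order so that
exclusion counts are reproducible:

1. window     — first SLE-coded visit after the study window end
2. prevalent  — first SLE-coded visit before the study window start
                (the pre-window register coverage acts as washout)
3. residency  — less than 2 years of residency before diagnosis
4. age        — younger than 18 at diagnosis
5. follow_up  — less than 1 year between diagnosis and registration end

Covariates follow the published categorisations: calendar cohort of
diagnosis (2005-2008 / 2009-2012 / 2013-2016 / 2017-2021), age category
(18-39 / 40-59 / >=60), hospital type of the diagnosing visit, and
utilization in the year before diagnosis (hospitalised days categorised
0 / 1-7 / >7; specialist outpatient visits 0-2 / 3-6 / >6). Hospital
stays that straddle the diagnosis date are clipped at it.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

from .codes import COHORT_PERIODS, SLE_ICD10, SPECIALIST_DEPARTMENTS

DAYS_PER_YEAR = 365.25
WITHIN_DAYS = 365  # "within 1 year" for the qualifying visit pair, inclusive
RESIDENCY_DAYS = 2 * DAYS_PER_YEAR
MIN_FOLLOWUP_DAYS = DAYS_PER_YEAR

_ICD_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")

AGE_CATEGORIES = ["18-39", "40-59", ">=60"]
HOSPITAL_DAY_CATEGORIES = ["0", "1-7", ">7"]
OUTPATIENT_CATEGORIES = ["0-2", "3-6", ">6"]

FILTER_ORDER = ["window", "prevalent", "residency", "age", "follow_up"]


def _explode_codes(visits: pd.DataFrame) -> pd.DataFrame:
    """One row per (visit, ICD code); malformed codes dropped with a warning."""
    codes = visits["icd_codes"].astype(str).str.split(";")
    out = visits.assign(icd=codes).explode("icd")
    out["icd"] = out["icd"].str.strip()
    bad = ~out["icd"].str.match(_ICD_RE) & (out["icd"] != "")
    if bad.any():
        examples = sorted(out.loc[bad, "icd"].unique()[:5])
        warnings.warn(f"ignoring {int(bad.sum())} malformed ICD codes "
                      f"(e.g. {examples})", stacklevel=3)
    return out[~bad]


def find_case_candidates(
    visits: pd.DataFrame,
    sle_codes=SLE_ICD10,
    specialist_departments=SPECIALIST_DEPARTMENTS,
) -> pd.DataFrame:
    """Identify case candidates and their candidate diagnosis dates.

    Returns a frame with columns ``person_id`` and ``candidate_date`` (the
    first SLE-coded visit ever) for persons with two SLE-coded visits at
    most :data:`WITHIN_DAYS` apart and at least one SLE-coded visit at a
    specialist department.
    """
    coded = _explode_codes(visits)
    sle = coded[coded["icd"].isin(set(sle_codes))]
    if sle.empty:
        return pd.DataFrame({"person_id": pd.Series(dtype=object),
                             "candidate_date": pd.Series(dtype="datetime64[ns]")})
    # one row per (person, visit): a visit may list several SLE codes
    sle = sle.drop_duplicates(subset=["person_id", "visit_date", "department"])
    sle = sle.sort_values(["person_id", "visit_date"], kind="stable")

    # minimum gap between any two visits = minimum consecutive gap when sorted
    same_person = sle["person_id"].eq(sle["person_id"].shift())
    gap = sle["visit_date"].diff().dt.days.where(same_person)
    min_gap = gap.groupby(sle["person_id"].to_numpy()).min()
    specialist = sle["department"].isin(set(specialist_departments))
    has_spec = specialist.groupby(sle["person_id"].to_numpy()).any()
    first_date = sle.groupby(sle["person_id"].to_numpy())["visit_date"].min()

    ok = (min_gap <= WITHIN_DAYS) & has_spec
    out = first_date[ok].rename("candidate_date").rename_axis("person_id").reset_index()
    return out.sort_values("person_id", kind="stable").reset_index(drop=True)


def _calendar_cohort(dates: pd.Series) -> pd.Series:
    year = dates.dt.year
    out = pd.Series(pd.NA, index=dates.index, dtype=object)
    for label, (y0, y1) in COHORT_PERIODS.items():
        out[(year >= y0) & (year <= y1)] = label
    return out


def apply_incidence_filters(
    candidates: pd.DataFrame,
    persons: pd.DataFrame,
    study_start="2005-07-01",
    study_end="2021-09-01",
    data_end="2024-01-31",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the incidence filters; return (cohort entries, exclusion log).

    The exclusion log has one count per filter reason, in application
    order, plus the retained count; the counts sum to the candidate count.
    """
    study_start, study_end, data_end = map(pd.Timestamp,
                                           (study_start, study_end, data_end))
    missing = set(candidates["person_id"]) - set(persons["person_id"])
    if missing:
        raise ValueError(
            "persons referenced by visits but missing from the population "
            f"table: {sorted(missing)[:10]}"
        )
    df = candidates.merge(persons, on="person_id", how="left")
    dx = df["candidate_date"]

    reasons = pd.Series("", index=df.index, dtype=object)
    checks = {
        "window": dx > study_end,
        "prevalent": dx < study_start,
        "residency": df["residency_start"] > dx - pd.Timedelta(days=RESIDENCY_DAYS),
        "age": (dx - df["birth_date"]).dt.days / DAYS_PER_YEAR < 18.0,
        "follow_up": (df["registration_end"] - dx).dt.days < MIN_FOLLOWUP_DAYS,
    }
    for name in FILTER_ORDER:
        mask = checks[name] & (reasons == "")
        reasons[mask] = name

    retained = df[reasons == ""].copy()
    retained = retained.rename(columns={"candidate_date": "diagnosis_date"})
    retained["follow_up_end"] = retained["registration_end"].clip(upper=data_end)
    retained["follow_up_years"] = (
        (retained["follow_up_end"] - retained["diagnosis_date"]).dt.days / DAYS_PER_YEAR)
    retained["age_at_diagnosis"] = (
        (retained["diagnosis_date"] - retained["birth_date"]).dt.days / DAYS_PER_YEAR)
    retained["age_category"] = pd.cut(
        retained["age_at_diagnosis"], bins=[18, 40, 60, np.inf],
        labels=AGE_CATEGORIES, right=False).astype(object)
    retained["calendar_cohort"] = _calendar_cohort(retained["diagnosis_date"])

    counts = [(name, int((reasons == name).sum())) for name in FILTER_ORDER]
    counts.append(("retained", len(retained)))
    exclusions = pd.DataFrame(counts, columns=["reason", "count"])

    cols = ["person_id", "diagnosis_date", "calendar_cohort", "age_at_diagnosis",
            "age_category", "sex", "education", "birth_region",
            "follow_up_end", "follow_up_years"]
    return retained[cols].reset_index(drop=True), exclusions


def derive_covariates(
    cohort: pd.DataFrame,
    visits: pd.DataFrame,
    sle_codes=SLE_ICD10,
    specialist_departments=SPECIALIST_DEPARTMENTS,
) -> pd.DataFrame:
    """Complete cohort entries with utilization covariates and the
    hospital type of the diagnosing visit."""
    out = cohort.copy()
    v = visits.merge(out[["person_id", "diagnosis_date"]], on="person_id",
                     how="inner")

    # hospital days: stays admitted in the year before diagnosis, clipped at it
    stays = v[v["inpatient"].astype(bool)].copy()
    adm = stays["visit_date"]
    in_window = (adm >= stays["diagnosis_date"] - pd.Timedelta(days=365)) & \
                (adm < stays["diagnosis_date"])
    stays = stays[in_window]
    clipped_end = stays[["discharge_date", "diagnosis_date"]].min(axis=1)
    stays["days"] = (clipped_end - stays["visit_date"]).dt.days
    hosp_days = stays.groupby("person_id")["days"].sum()
    out["prior_hospital_days"] = out["person_id"].map(hosp_days).fillna(0).astype(int)
    out["prior_hospital_days_cat"] = pd.cut(
        out["prior_hospital_days"], bins=[-1, 0, 7, np.inf],
        labels=HOSPITAL_DAY_CATEGORIES).astype(object)

    outp = v[~v["inpatient"].astype(bool)]
    in_window = (outp["visit_date"] >= outp["diagnosis_date"] - pd.Timedelta(days=365)) & \
                (outp["visit_date"] < outp["diagnosis_date"])
    outp = outp[in_window & outp["department"].isin(set(specialist_departments))]
    n_outp = outp.groupby("person_id").size()
    out["prior_outpatient_visits"] = out["person_id"].map(n_outp).fillna(0).astype(int)
    out["prior_outpatient_visits_cat"] = pd.cut(
        out["prior_outpatient_visits"], bins=[-1, 2, 6, np.inf],
        labels=OUTPATIENT_CATEGORIES).astype(object)

    # hospital type of the first SLE-coded visit
    coded = _explode_codes(v)
    sle = coded[coded["icd"].isin(set(sle_codes))]
    sle = sle.sort_values(["person_id", "visit_date"], kind="stable")
    first = sle.groupby("person_id").first()["hospital_type"]
    out["diagnosis_hospital"] = out["person_id"].map(first)
    return out


def build_cohort(
    persons: pd.DataFrame,
    visits: pd.DataFrame,
    study_start="2005-07-01",
    study_end="2021-09-01",
    data_end="2024-01-31",
    sle_codes=SLE_ICD10,
    specialist_departments=SPECIALIST_DEPARTMENTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cohort construction: candidates -> filters -> covariates."""
    candidates = find_case_candidates(visits, sle_codes, specialist_departments)
    cohort, exclusions = apply_incidence_filters(
        candidates, persons, study_start, study_end, data_end)
    cohort = derive_covariates(cohort, visits, sle_codes, specialist_departments)
    return cohort, exclusions
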