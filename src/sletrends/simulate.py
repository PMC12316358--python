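"""Synthetic Swedish-register generator.

Emulates the three register-shaped tables the pipeline consumes — a
population table (Total Population Register shape), a care-visit table
(National Patient Register shape) and a dispensation table (Prescribed
Drug Register shape) — for a cohort of incident SLE cases with known,
configurable ground truth:

* latent severity (lognormal) scales both pre-diagnosis healthcare
  utilization and cumulative glucocorticoid dose;
* per calendar cohort of diagnosis, the 5-year cumulative
  prednisolone-equivalent GC dose is lognormal with configured median,
  spread over treated years with a geometric taper (highest dose in the
  first year, consistent with observed tapering);
* hydroxychloroquine is initiated shortly after diagnosis with a
  cohort-specific probability, refilled every ~100 days (uniform 80-120,
  so realised PDC < 1 even for persistent users) until an exponential
  discontinuation time;
* immunosuppressant use with a fixed class mix (AZA/MTX/MMF dominating).

A configurable share of cases is "injected" to violate each eligibility
filter (prevalent disease, age < 18, recent immigration, a single SLE
visit, no specialist visit); the ground-truth table records the expected
verdict so the cohort builder can be validated decision-by-decision.

Identical configuration (including seed) yields bit-identical tables.
"""

from __future__ import annotations

import json
from functools import lru_cache
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .codes import HCQ_ATC, SPECIALIST_DEPARTMENTS
from .config import SimulationConfig

DAYS_PER_YEAR = 365.25

#: non-SLE ICD-10 codes used for background/utilization visits
_BACKGROUND_ICD = np.array(["R53.9", "M79.7", "N05.9", "D69.9", "I10.9", "J45.9"])
_SLE_ICD = np.array(["M32.9", "M32.1", "M32.8"])
_SLE_ICD_P = np.array([0.70, 0.15, 0.15])
_DEPT_P = np.array([0.60, 0.10, 0.10, 0.15, 0.05])  # over SPECIALIST_DEPARTMENTS

#: generator-side GC substances: ATC -> (strength mg/pill, equivalence factor, DDD mg)
_GC_SUBSTANCES = {
    "H02AB06": (5.0, 1.0, 10.0),
    "H02AB04": (4.0, 1.25, 7.5),
    "H02AB07": (5.0, 1.0, 10.0),
}

#: IS classes: label -> (ATC, strength mg, DDD mg, pills/package, mix probability)
_IS_CATALOGUE = {
    "IS:AZA": ("L04AX01", 50.0, 150.0, 100, 0.38),
    "IS:MTX": ("L04AX03", 2.5, 2.5, 30, 0.33),
    "IS:MMF": ("L04AA06", 500.0, 2000.0, 100, 0.15),
    "IS:CYC": ("L01AA01", 50.0, 100.0, 50, 0.04),
    "IS:LEF": ("L04AA13", 20.0, 20.0, 30, 0.03),
    "IS:TAC": ("L04AD02", 1.0, 5.0, 50, 0.04),
    "IS:CSA": ("L04AD01", 100.0, 250.0, 50, 0.03),
}


class SimulatedRegisters(NamedTuple):
    persons: pd.DataFrame
    visits: pd.DataFrame
    dispensations: pd.DataFrame
    ground_truth: pd.DataFrame


def _cohort_periods(config: SimulationConfig):
    """Clip configured cohort periods to the study window; return labels,
    period start dates and lengths in days (inclusive of both ends)."""
    from .codes import COHORT_PERIODS

    labels, starts, ndays = [], [], []
    start_ts = pd.Timestamp(config.study_start)
    end_ts = pd.Timestamp(config.study_end)
    for label in sorted(config.cohort_effects):
        y0, y1 = COHORT_PERIODS[label]
        lo = max(start_ts, pd.Timestamp(y0, 1, 1))
        hi = min(end_ts, pd.Timestamp(y1, 12, 31))
        n = (hi - lo).days + 1
        if n > 0:
            labels.append(label)
            starts.append(lo)
            ndays.append(n)
    if not labels:
        raise ValueError("no cohort period overlaps the study window")
    return labels, pd.to_datetime(starts), np.asarray(ndays, dtype=float)


def _truncnorm_ppf(u, mean, sd, lo, hi):
    from scipy import stats

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _simulate(config: SimulationConfig) -> SimulatedRegisters:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_persons
    demo, util = config.demography, config.utilization
    data_end = pd.Timestamp(config.data_end)
    study_start = pd.Timestamp(config.study_start)

    person_id = np.array([f"P{i:06d}" for i in range(n)])

    # --- latent person-level structure -------------------------------------
    labels, period_starts, period_days = _cohort_periods(config)
    probs = period_days / period_days.sum()
    ci = rng.choice(len(labels), size=n, p=probs)
    dx_offset = np.floor(rng.random(n) * period_days[ci]).astype(int)
    dx = period_starts[ci] + pd.to_timedelta(dx_offset, unit="D")
    cohort = np.asarray(labels, dtype=object)[ci]

    is_case = rng.random(n) < config.case_fraction
    u_viol = rng.random(n)
    edges = np.cumsum([
        config.prevalent_fraction, config.underage_fraction,
        config.recent_immigrant_fraction, config.single_visit_fraction,
        config.no_specialist_fraction,
    ])
    viol = np.full(n, "", dtype=object)
    names = ["prevalent", "underage", "recent_immigrant", "single_visit",
             "no_specialist"]
    lo = 0.0
    for name, hi in zip(names, edges):
        viol[(u_viol >= lo) & (u_viol < hi)] = name
        lo = hi
    viol[~is_case] = ""

    sex = np.where(rng.random(n) < demo.female_prob, "female", "male")
    u_region = rng.random(n)
    region = np.full(n, "Nordic", dtype=object)
    region[u_region < demo.non_nordic_prob] = "non-Nordic"
    region[(u_region >= demo.non_nordic_prob)
           & (u_region < demo.non_nordic_prob + demo.missing_region_prob)] = "missing"
    region[viol == "recent_immigrant"] = "non-Nordic"

    edu_levels = list(demo.education_probs)
    education = rng.choice(edu_levels, size=n, p=list(demo.education_probs.values()))

    severity = rng.lognormal(0.0, util.severity_sigma, n)

    age = _truncnorm_ppf(rng.random(n), demo.age_mean, demo.age_sd,
                         demo.age_min, demo.age_max)
    age_underage = rng.uniform(8.0, 17.5, n)
    age = np.where(viol == "underage", age_underage, age)
    birth_date = dx - pd.to_timedelta(np.round(age * DAYS_PER_YEAR).astype(int), "D")

    res_years = rng.uniform(2.5, 30.0, n)
    res_recent = rng.uniform(0.75, 1.9, n)
    res_years = np.where(viol == "recent_immigrant", res_recent, res_years)
    residency_start = dx - pd.to_timedelta(
        np.round(res_years * DAYS_PER_YEAR).astype(int), "D")
    residency_start = np.where(region == "non-Nordic",
                               residency_start.values, birth_date.values)
    residency_start = pd.DatetimeIndex(np.maximum(residency_start,
                                                  birth_date.values))

    total_rate = config.censoring.death_rate + config.censoring.emigration_rate
    scale = 1.0 / total_rate if total_rate > 0 else np.inf
    censor_years = rng.exponential(scale, n) if np.isfinite(scale) else np.full(n, np.inf)
    censor_days = np.minimum(np.round(censor_years * DAYS_PER_YEAR), 40_000).astype(int)
    registration_end = pd.DatetimeIndex(np.minimum(
        (dx + pd.to_timedelta(censor_days, "D")).values,
        np.datetime64(data_end, "ns")))

    fu_days = (registration_end - dx).days.to_numpy()

    # realised eligibility verdicts, in the cohort builder's filter order
    reason = np.full(n, "", dtype=object)
    reason[~is_case] = "non_case"
    m = is_case & np.isin(viol, ["single_visit", "no_specialist"])
    reason[m] = "not_candidate"
    m = is_case & (reason == "") & (viol == "prevalent")
    reason[m] = "prevalent"
    res_short = (dx - residency_start).days.to_numpy() < 2 * DAYS_PER_YEAR
    m = is_case & (reason == "") & res_short
    reason[m] = "residency"
    real_age = (dx - birth_date).days.to_numpy() / DAYS_PER_YEAR
    m = is_case & (reason == "") & (real_age < 18.0)
    reason[m] = "age"
    m = is_case & (reason == "") & (fu_days < DAYS_PER_YEAR)
    reason[m] = "follow_up"
    eligible = is_case & (reason == "")

    persons = pd.DataFrame({
        "person_id": person_id,
        "sex": sex,
        "birth_date": birth_date,
        "birth_region": region,
        "education": education,
        "residency_start": residency_start,
        "registration_end": registration_end,
    })

    visits = _make_visits(config, rng, person_id, dx, is_case, viol, severity,
                          fu_days, registration_end)

    disp, gt_drugs = _make_dispensations(config, rng, person_id, dx, cohort,
                                         is_case, severity, registration_end)

    ground_truth = pd.DataFrame({
        "person_id": person_id,
        "is_case": is_case,
        "violation": viol,
        "eligible": eligible,
        "ineligible_reason": reason,
        "severity": severity,
        "diagnosis_date": pd.DatetimeIndex(np.where(
            is_case, dx.values, np.datetime64("NaT", "ns"))),
        "calendar_cohort": np.where(is_case, cohort, ""),
        **gt_drugs,
    })

    return SimulatedRegisters(persons, visits, disp, ground_truth)


def _make_visits(config, rng, person_id, dx, is_case, viol, severity,
                 fu_days, registration_end):
    util = config.utilization
    study_start = pd.Timestamp(config.study_start)
    n = len(person_id)
    case_idx = np.flatnonzero(is_case)

    blocks = []

    def block(idx, dates, icd, dept, hospital, inpatient, discharge=None):
        nb = len(idx)
        if nb == 0:
            return
        blocks.append(pd.DataFrame({
            "person_id": person_id[idx],
            "visit_date": pd.DatetimeIndex(dates),
            "icd_codes": icd,
            "department": dept,
            "hospital_type": hospital,
            "inpatient": inpatient,
            "discharge_date": pd.DatetimeIndex(discharge) if discharge is not None
            else pd.DatetimeIndex([pd.NaT] * nb),
        }))

    spec = np.asarray(SPECIALIST_DEPARTMENTS, dtype=object)

    # diagnosis visit (first SLE-coded visit)
    nc = len(case_idx)
    dept1 = rng.choice(spec, size=nc, p=_DEPT_P)
    dept1 = np.where(viol[case_idx] == "no_specialist", "other", dept1)
    hosp1 = np.where(rng.random(nc) < 0.49, "university", "other")
    icd1 = rng.choice(_SLE_ICD, size=nc, p=_SLE_ICD_P).astype(object)
    extra = rng.random(nc) < 0.3
    icd1[extra] = icd1[extra] + ";" + rng.choice(_BACKGROUND_ICD, size=int(extra.sum()))
    inp1 = rng.random(nc) < 0.12
    los1 = 1 + np.floor(rng.exponential(util.hospital_los_mean_days, nc)).astype(int)
    disch1 = pd.DatetimeIndex(np.where(
        inp1, dx[case_idx] + pd.to_timedelta(los1, "D"), pd.NaT))
    block(case_idx, dx[case_idx], icd1, dept1, hosp1, inp1, disch1)

    # second qualifying SLE visit, within 300 days (clipped to registration end)
    pair = case_idx[viol[case_idx] != "single_visit"]
    off2 = np.round(rng.uniform(14, 300, len(case_idx))).astype(int)
    off2 = off2[viol[case_idx] != "single_visit"]
    off2 = np.minimum(off2, fu_days[pair])
    d2 = dx[pair] + pd.to_timedelta(off2, "D")
    spec2 = rng.choice(spec, size=len(case_idx), p=_DEPT_P)[viol[case_idx] != "single_visit"]
    other2 = rng.random(len(case_idx))[viol[case_idx] != "single_visit"] < 0.5
    dept2 = np.where(other2, "other", spec2)
    dept2 = np.where(viol[pair] == "no_specialist", "other", dept2)
    hosp2 = np.where(rng.random(len(pair)) < 0.49, "university", "other")
    icd2 = rng.choice(_SLE_ICD, size=len(pair), p=_SLE_ICD_P)
    block(pair, d2, icd2, dept2, hosp2, np.zeros(len(pair), bool))

    # pre-window SLE visit for prevalent cases
    prev = np.flatnonzero(is_case & (viol == "prevalent"))
    offp = np.round(rng.uniform(180, 1600, len(prev))).astype(int)
    dp = study_start - pd.to_timedelta(offp, "D")
    deptp = rng.choice(spec, size=len(prev), p=_DEPT_P)
    hospp = np.where(rng.random(len(prev)) < 0.49, "university", "other")
    block(prev, dp, np.full(len(prev), "M32.9", dtype=object), deptp, hospp,
          np.zeros(len(prev), bool))

    # later SLE-coded follow-up visits (suppressed for candidacy-violating cases)
    fu_years = np.maximum(fu_days, 0) / DAYS_PER_YEAR
    rate = util.sle_visit_rate * fu_years
    rate[~is_case | np.isin(viol, ["single_visit", "no_specialist"])] = 0.0
    counts = rng.poisson(rate)
    rep = np.repeat(np.arange(n), counts)
    offs = np.ceil(rng.random(len(rep)) * np.maximum(fu_days[rep], 1)).astype(int)
    dlate = dx[rep] + pd.to_timedelta(offs, "D")
    specl = rng.choice(spec, size=len(rep), p=_DEPT_P)
    deptl = np.where(rng.random(len(rep)) < 0.4, "other", specl)
    hospl = np.where(rng.random(len(rep)) < 0.49, "university", "other")
    icdl = rng.choice(_SLE_ICD, size=len(rep), p=_SLE_ICD_P)
    block(rep, dlate, icdl, deptl, hospl, np.zeros(len(rep), bool))

    # pre-diagnosis specialist outpatient visits (severity-correlated)
    mean = util.outpatient_mean * severity ** 0.7
    k = util.outpatient_dispersion
    p = k / (k + np.maximum(mean, 1e-9))
    counts = np.where(is_case, rng.negative_binomial(k, p), 0)
    rep = np.repeat(np.arange(n), counts)
    offs = np.ceil(rng.random(len(rep)) * 365).astype(int)  # 1..365 days before dx
    dout = dx[rep] - pd.to_timedelta(offs, "D")
    dept = rng.choice(spec, size=len(rep), p=_DEPT_P)
    hosp = np.where(rng.random(len(rep)) < 0.49, "university", "other")
    icd = rng.choice(_BACKGROUND_ICD, size=len(rep))
    block(rep, dout, icd, dept, hosp, np.zeros(len(rep), bool))

    # pre-diagnosis hospitalizations; stays may run past the diagnosis date
    rate = util.hospitalization_rate * severity ** 0.5
    counts = np.where(is_case, rng.poisson(rate), 0)
    rep = np.repeat(np.arange(n), counts)
    offs = np.ceil(rng.random(len(rep)) * 364).astype(int) + 1
    adm = dx[rep] - pd.to_timedelta(offs, "D")
    los = 1 + np.floor(rng.exponential(util.hospital_los_mean_days, len(rep))).astype(int)
    disch = adm + pd.to_timedelta(los, "D")
    hosp = np.where(rng.random(len(rep)) < 0.49, "university", "other")
    icd = rng.choice(_BACKGROUND_ICD, size=len(rep))
    block(rep, adm, icd, np.full(len(rep), "internal medicine", dtype=object),
          hosp, np.ones(len(rep), bool), disch)

    # background visits for non-cases
    span_years = np.maximum(
        (registration_end - study_start).days.to_numpy(), 0) / DAYS_PER_YEAR
    counts = np.where(~is_case, rng.poisson(util.background_visit_rate * span_years), 0)
    rep = np.repeat(np.arange(n), counts)
    offs = np.floor(rng.random(len(rep))
                    * np.maximum(span_years[rep] * DAYS_PER_YEAR, 1)).astype(int)
    dbg = study_start + pd.to_timedelta(offs, "D")
    dept = rng.choice(np.append(spec, "other"), size=len(rep))
    hosp = np.where(rng.random(len(rep)) < 0.49, "university", "other")
    icd = rng.choice(_BACKGROUND_ICD, size=len(rep))
    block(rep, dbg, icd, dept, hosp, np.zeros(len(rep), bool))

    visits = pd.concat(blocks, ignore_index=True)
    visits = visits.sort_values(
        ["person_id", "visit_date", "department"], kind="stable").reset_index(drop=True)
    return visits


def _make_dispensations(config, rng, person_id, dx, cohort, is_case, severity,
                        registration_end):
    n = len(person_id)
    data_end = pd.Timestamp(config.data_end)
    end_limit = pd.DatetimeIndex(np.minimum(registration_end.values,
                                            np.datetime64(data_end, "ns")))
    end_days = (end_limit - dx).days.to_numpy()  # dispensing horizon after dx

    eff = {lab: config.cohort_effects[lab] for lab in config.cohort_effects}
    med = np.array([eff[c].gc_median_5yr_dose_mg if c else np.nan for c in cohort])
    scale = np.array([eff[c].gc_scale if c else np.nan for c in cohort])
    init_p = np.array([eff[c].hcq_initiation_prob if c else 0.0 for c in cohort])
    haz = np.array([eff[c].hcq_discontinuation_hazard if c else 0.0 for c in cohort])
    is_p = np.array([eff[c].is_use_prob if c else 0.0 for c in cohort])

    frames = []

    # ---- glucocorticoids ---------------------------------------------------
    gcp = config.gc
    gc_user = is_case & (rng.random(n) < gcp.user_prob)
    z = np.log(severity) / config.utilization.severity_sigma
    cum_dose = med * np.exp(scale * z)  # true 5-year cumulative dose, mg PE

    start_year = np.where(rng.random(n) < gcp.year1_start_prob, 1,
                          rng.integers(2, 6, n))
    dur = rng.geometric(gcp.stop_prob, n)
    last_year = np.minimum(5, start_year + dur - 1)

    years = np.arange(1, 6)
    mask = (years[None, :] >= start_year[:, None]) & (years[None, :] <= last_year[:, None])
    w = np.where(mask, gcp.taper ** (years[None, :] - start_year[:, None]), 0.0)
    w = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-12)
    year_dose = cum_dose[:, None] * w
    year_dose[~gc_user] = 0.0

    atc_choices = np.array(list(_GC_SUBSTANCES), dtype=object)
    gc_atc = rng.choice(atc_choices, size=n, p=[0.88, 0.07, 0.05])

    m = np.clip(np.round(year_dose / gcp.fill_dose_mg), 1, 12).astype(int)
    m[year_dose <= 0] = 0
    mflat = m.ravel()
    pidx = np.repeat((np.arange(n)[:, None] * np.ones(5, int)[None, :]).ravel(), mflat)
    yidx = np.repeat((years[None, :] * np.ones(n, int)[:, None]).ravel(), mflat)
    fill_dose = np.repeat((year_dose / np.maximum(m, 1)).ravel(), mflat)
    off = (yidx - 1) * DAYS_PER_YEAR + rng.uniform(0, DAYS_PER_YEAR, len(pidx))
    off = np.floor(off).astype(int)
    keep = off <= end_days[pidx]
    pidx, fill_dose, off = pidx[keep], fill_dose[keep], off[keep]
    atc = gc_atc[pidx]
    strength = np.array([_GC_SUBSTANCES[a][0] for a in atc])
    factor = np.array([_GC_SUBSTANCES[a][1] for a in atc])
    ddd_mg = np.array([_GC_SUBSTANCES[a][2] for a in atc])
    n_ddd = fill_dose / (ddd_mg * factor)
    pills = fill_dose / factor / strength
    frames.append(pd.DataFrame({
        "person_id": person_id[pidx],
        "fill_date": pd.DatetimeIndex(dx[pidx]) + pd.to_timedelta(off, "D"),
        "atc_code": atc,
        "n_packages": np.maximum(1, np.round(pills / 100)).astype(int),
        "pills_per_package": 100,
        "strength_mg": strength,
        "n_ddd": n_ddd,
    }))

    # ---- hydroxychloroquine ------------------------------------------------
    hcqp = config.hcq
    initiated = is_case & (rng.random(n) < init_p)
    delay = np.floor(rng.uniform(0, hcqp.start_delay_max_days + 1e-12, n)).astype(int)
    pers_scale = np.where(haz > 0, 1.0 / np.maximum(haz, 1e-12), 1e6)
    pers_days = rng.exponential(pers_scale) * DAYS_PER_YEAR

    horizon = (data_end - pd.Timestamp(config.study_start)).days
    lo, hi = hcqp.refill_gap_days
    max_fills = int(horizon / lo) + 2
    idx = np.flatnonzero(initiated)
    gaps = rng.uniform(lo, hi, size=(len(idx), max_fills))
    offs = np.concatenate([np.zeros((len(idx), 1)), np.cumsum(gaps, axis=1)], axis=1)
    two_pack = rng.random((len(idx), max_fills + 1)) < hcqp.two_package_prob
    keep = offs < pers_days[idx][:, None]
    fill_off = delay[idx][:, None] + np.floor(offs).astype(int)
    keep &= fill_off <= end_days[idx][:, None]
    rows, cols = np.nonzero(keep)
    p = idx[rows]
    packages = np.where(two_pack[rows, cols], 2, 1)
    frames.append(pd.DataFrame({
        "person_id": person_id[p],
        "fill_date": pd.DatetimeIndex(dx[p]) + pd.to_timedelta(fill_off[rows, cols], "D"),
        "atc_code": HCQ_ATC,
        "n_packages": packages,
        "pills_per_package": 100,
        "strength_mg": 200.0,
        "n_ddd": packages * 100 * 200.0 / 516.0,
    }))

    # ---- immunosuppressants ------------------------------------------------
    is_user = is_case & (rng.random(n) < is_p)
    classes = np.array(list(_IS_CATALOGUE), dtype=object)
    mix = np.array([_IS_CATALOGUE[c][4] for c in classes])
    is_class = rng.choice(classes, size=n, p=mix / mix.sum())
    is_delay = np.floor(rng.uniform(0, 365, n)).astype(int)
    is_days = rng.exponential(4.0, n) * DAYS_PER_YEAR
    idx = np.flatnonzero(is_user)
    max_fills = int(horizon / 75) + 2
    gaps = rng.uniform(75, 105, size=(len(idx), max_fills))
    offs = np.concatenate([np.zeros((len(idx), 1)), np.cumsum(gaps, axis=1)], axis=1)
    keep = offs < is_days[idx][:, None]
    fill_off = is_delay[idx][:, None] + np.floor(offs).astype(int)
    keep &= fill_off <= end_days[idx][:, None]
    rows, cols = np.nonzero(keep)
    p = idx[rows]
    atc = np.array([_IS_CATALOGUE[c][0] for c in is_class[p]], dtype=object)
    strength = np.array([_IS_CATALOGUE[c][1] for c in is_class[p]])
    ddd_mg = np.array([_IS_CATALOGUE[c][2] for c in is_class[p]])
    ppk = np.array([_IS_CATALOGUE[c][3] for c in is_class[p]])
    frames.append(pd.DataFrame({
        "person_id": person_id[p],
        "fill_date": pd.DatetimeIndex(dx[p]) + pd.to_timedelta(fill_off[rows, cols], "D"),
        "atc_code": atc,
        "n_packages": 1,
        "pills_per_package": ppk,
        "strength_mg": strength,
        "n_ddd": ppk * strength / ddd_mg,
    }))

    disp = pd.concat(frames, ignore_index=True)
    from .codes import ATC_CLASSES

    disp["drug_class"] = disp["atc_code"].map(ATC_CLASSES)
    disp = disp.sort_values(["person_id", "fill_date", "atc_code"],
                            kind="stable").reset_index(drop=True)
    disp = disp[["person_id", "fill_date", "atc_code", "drug_class", "n_packages",
                 "pills_per_package", "strength_mg", "n_ddd"]]

    gt_drugs = {
        "gc_user": gc_user,
        "true_gc_5yr_dose_mg": np.where(gc_user, cum_dose, 0.0),
        "gc_start_year": np.where(gc_user, start_year, 0),
        "gc_last_year": np.where(gc_user, last_year, 0),
        "hcq_initiated": initiated,
        "hcq_start_delay_days": np.where(initiated, delay, -1),
        "hcq_persistence_years": np.where(initiated, pers_days / DAYS_PER_YEAR, np.nan),
        "is_user": is_user,
        "is_class": np.where(is_user, is_class, ""),
    }
    return disp, gt_drugs


@lru_cache(maxsize=4)
def _simulate_cached(config_json: str) -> SimulatedRegisters:
    return _simulate(SimulationConfig(**json.loads(config_json)))


def simulate_registers(config: SimulationConfig) -> SimulatedRegisters:
    """Generate all four tables for one configuration. Deterministic in
    ``config`` (including its seed)."""
    res = _simulate_cached(config.model_dump_json())
    return SimulatedRegisters(*(df.copy() for df in res))


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Population table: one row per person (demographics, residency,
    education, registration end)."""
    return simulate_registers(config).persons


def generate_visits(persons: pd.DataFrame, config: SimulationConfig):
    """Care-visit table plus the ground-truth table for the same draw."""
    if len(persons) == 0:
        raise ValueError("persons must be non-empty")
    regs = simulate_registers(config)
    if not persons["person_id"].isin(regs.persons["person_id"]).all():
        raise ValueError("persons do not match the configured simulation draw")
    return regs.visits, regs.ground_truth


def generate_dispensations(persons: pd.DataFrame, ground_truth: pd.DataFrame,
                           config: SimulationConfig) -> pd.DataFrame:
    """Dispensation table for the same draw."""
    if "diagnosis_date" not in ground_truth:
        raise ValueError("ground truth lacks diagnosis dates")
    return simulate_registers(config).dispensations


# ---------------------------------------------------------------------------
# serialization

_DATE_COLS = {
    "persons": ["birth_date", "residency_start", "registration_end"],
    "visits": ["visit_date", "discharge_date"],
    "dispensations": ["fill_date"],
    "ground_truth": ["diagnosis_date"],
}


def write_registers(regs: SimulatedRegisters, outdir) -> dict[str, Path]:
    """Write the four tables as CSV with ISO-8601 dates; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in regs._asdict().items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, date_format="%Y-%m-%d")
        paths[name] = path
    return paths


def _read(path, date_cols) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=date_cols)


def read_population(path) -> pd.DataFrame:
    return _read(path, _DATE_COLS["persons"])


def read_visits(path) -> pd.DataFrame:
    return _read(path, _DATE_COLS["visits"])


def read_dispensations(path) -> pd.DataFrame:
    return _read(path, _DATE_COLS["dispensations"])
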