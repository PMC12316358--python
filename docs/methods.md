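# Methods

This note documents the models, the synthetic-data generating mechanism,
and the numerical conventions used throughout `sletrends`.

## Study design being emulated

The pipeline reproduces a register-based inception-cohort design: adults
with newly diagnosed SLE are identified from coded care visits, their
pharmacy dispensations are turned into longitudinal exposure measures, and
temporal trends across four calendar cohorts of diagnosis (2005–2008,
2009–2012, 2013–2016, 2017–2021) are estimated with regression models
adjusted for patient characteristics. Registration ends at death,
emigration or the administrative data end (2024-01-31); dispensation data
exist from 2005-07-01, which is also why the study window opens there —
the preceding 4.5 years of coded care act as a washout that removes
prevalent cases.

## Cohort definition and covariates

A person qualifies as a case when they have at least two SLE-coded visits
(ICD-10 M32.1, M32.8, M32.9) no more than 365 days apart ("within one
year" is read as ≤365 days, inclusive) and at least one of their SLE-coded
visits — not only of the qualifying pair — is at a specialist department
(rheumatology, dermatology, nephrology, internal medicine, paediatrics;
the list is configurable, and paediatric departments are retained even
though the cohort itself is adult). The diagnosis date is the first
SLE-coded visit ever; the second qualifying visit may fall after the
window closes.

Filters run in a fixed order — window, washout/prevalence, residency
(≥2 × 365.25 days), age (≥18 with age computed as days/365.25), follow-up
(≥365.25 days) — and each excluded person is counted once, at the first
failing filter, so exclusion logs are reproducible and sum to the
candidate count.

Hospitalised days in the year before diagnosis count stays *admitted* in
[dx−365 d, dx), each contributing min(discharge, dx) − admission days;
clipping at the diagnosis date is our choice, made so that post-diagnosis
bed-days cannot leak into a pre-diagnosis severity proxy. Specialist
outpatient visits are counted in the same window. Missing education and
birth region are explicit factor levels, never imputed.

## Exposure measures

**GC cumulative dose.** Each fill contributes `n_DDD` × DDD(substance) ×
potency-factor(substance) mg on the prednisolone scale, attributed wholly
to the window containing the fill date (no smearing; cumulative dose is a
property of what was dispensed, not a daily-dosing reconstruction). The
default equivalence table uses conventional potency ratios (prednisolone
and prednisone 1.0, methylprednisolone 1.25, dexamethasone 6.67,
betamethasone 8.33, hydrocortisone 0.25, cortisone 0.2) and WHO DDD
values; both are configurable and should be replaced when a
study-specific table exists. Only oral systemic GC (ATC H02AB) is
classed as GC by default; infusions and in-hospital medication are out
of scope.

**HCQ coverage.** Same-day fills are merged (packages summed) before the
package rule is applied — the data carry no within-day order, so any
other choice would be arbitrary. A one-package dispensation covers 100
days; a multi-package dispensation covers 75 days per package. When a new
fill arrives before the current supply runs out, the current supply is
treated as fully consumed at that moment and coverage continues from the
new fill (truncation, not stockpiling; a stockpiling variant is available
behind `stockpiling=True` for sensitivity analyses). Coverage is truncated
at end of follow-up. PDC is covered days divided by follow-up days in the
window.

Note one consequence of the truncation rule: total covered days is *not*
monotone in the fill stream once multi-package supplies exist — a
150-day, two-package supply followed one day later by a one-package fill
yields 1 + 100 days. Monotonicity does hold for single-package streams,
and that restricted form is what the property tests assert. (The 75-day
constant is taken as authoritative; the gloss that equates it with a
mg/day figure is arithmetically inconsistent with 100 × 200 mg packages
and is ignored.)

**Windows.** Year *k* after diagnosis is [dx+(k−1)·365.25 d, dx+k·365.25 d),
half-open, truncated at follow-up end; the 5-year summary window is their
union, so yearly doses and covered days sum to the 5-year values by
construction. Dispensations before diagnosis are excluded everywhere.

## Trend models

**Logistic any-use.** Any-use of GC/HCQ in year 1 (everyone; the cohort
already requires one year of follow-up) and year 5 (persons with ≥5 years
of follow-up *and* diagnosis by 2016-12-31 — the last calendar cohort is
not fully enrolled for 5-year outcomes and is excluded from those
analyses). Maximum-likelihood fits via statsmodels with the full
categorical adjustment set (calendar cohort, age category, sex,
education, birth region, diagnosis hospital, prior hospitalised days,
prior outpatient visits; first level of each factor is the reference);
Wald 95% CIs and p-values. Non-convergence (separation) and rank
deficiency are hard errors, not warnings.

**Wilcoxon rank-sum.** Midranks; exact two-sided p by full enumeration of
group assignments whenever C(n+m, min(n,m)) ≤ 200,000, otherwise a normal
approximation with tie-corrected variance and continuity correction; a
pooled sample with zero rank variance returns p = 1. Two-sided p is
2·min(lower tail, upper tail), capped at 1.

**Quantile regression.** For each τ in 0.10…0.90 (5% steps) the
coefficients minimise the check loss Σ ρ_τ(y − Xβ). The reference solver
is the LP dual — maximise y′a subject to X′a = (1−τ)X′1, 0 ≤ a ≤ 1,
solved with HiGHS; the equality multipliers are β. Ties among minimisers
are resolved by evaluating at τ − 10⁻⁶: β(τ) is a step function of τ, so
this deterministically returns the left-limit vertex, which for an
intercept-only design is the lowest minimiser (the inverted-CDF sample
quantile). Two fast paths compute the same estimator: (i) when the design
has exactly p distinct rows (saturated — e.g. intercept plus one
categorical factor) the loss separates by cell and per-cell inverted-CDF
quantiles are the exact minimiser under the same tie rule; (ii) for
bootstrap resampling, where tens of thousands of refits are needed, a
Schlossmacher-type IRLS approximation is the default (`boot_solver`
switches back to the exact LP). IRLS agrees with the LP to ~10⁻⁵ of the
optimal loss; near-flat objectives (extreme τ, small n) can put its
coefficients anywhere inside the optimal face, which is immaterial for
percentile CIs but is why point estimates always use the LP.

**Bootstrap.** Nonparametric person-level resampling, percentile CIs at
the 90% level (n_boot = 500 by default, minimum 100), seeded and
reproducible; the bootstrap standard error is reported alongside.
Replicates with a degenerate design (an unsampled factor level) are
dropped and counted; more than 10% dropped is an error. No
multiple-testing adjustment is made across the τ grid — each τ is
reported with its own CI, deliberately.

## Synthetic registers

No generative model exists for the real registers, so the generator is a
design artifact built to (a) reproduce the published marginals and (b)
expose every quantity downstream stages must recover.

- **Severity.** A lognormal latent severity (σ = 0.6) scales
  pre-diagnosis hospitalisation, outpatient-visit counts and GC dose,
  creating the confounding-by-indication structure the adjusted models
  face in real data.
- **GC.** A person is ever-user with probability 0.87. The true 5-year
  cumulative dose is lognormal around the configured cohort median
  (7500/7000/6500 mg for 2005–2008/2009–2012/2013–2016; σ = 1.028
  reproduces the published interquartile ratio of 4; the unobservable
  2017–2021 median is set to 6000 mg by trend extrapolation). The dose is
  spread over a treated span (start year 1 with probability 0.8,
  per-year stopping probability 0.13) with a geometric taper (ratio 0.6),
  so the first treated year carries the highest average daily dose.
  Fills carry `n_DDD` consistent with the prednisolone-equivalent dose,
  so the exposure engine recovers the generator-side truth exactly for
  uncensored persons. A lognormal cannot match the published quartiles
  and median simultaneously (the printed distribution is less
  right-skewed); the median is anchored and the IQR ratio approximated.
- **HCQ.** Initiation within 60 days of diagnosis with cohort
  probabilities 0.45/0.64/0.73/0.80; refills every Uniform(80, 120) days
  (so realised PDC < 1 even for fully persistent users, giving the
  quantile models a full PDC distribution); a 10% chance of a two-package
  fill exercises the 75-day rule; discontinuation is exponential with
  cohort hazards 0.285/0.21/0.18/0.12 per year, back-solved so the median
  5-year PDC among users matches the published 50.2/66.8/76.9%.
- **IS.** Cohort-specific use probability (0.45→0.60) with a fixed class
  mix dominated by azathioprine, methotrexate and mycophenolate.
- **Eligibility injections.** Configurable fractions of cases violate
  exactly one filter each (prevalent pre-window visit, age < 18, < 2 years
  residency, a single SLE visit, no specialist visit), and the
  ground-truth table records the expected verdict, so the cohort builder
  can be validated decision by decision.
- **Censoring.** Death and emigration are separate exponential hazards
  (0.015 and 0.025 per year combined); their true mix in the emulated
  registers is unknown, so both are exposed as knobs without claiming a
  real split. Censoring is independent of severity, which keeps the
  configured dose medians interpretable as estimands in the ≥5-year
  subset.
- **Incidence.** Diagnosis dates are uniform within each configured
  cohort period; the published cohort sizes are close to proportional to
  period length, so no additional calendar trend is modelled.
- **Determinism.** All draws come from one numpy Generator seeded by the
  config seed, in a fixed order; identical configuration gives
  bit-identical tables after serialization.

**What the generator does not emulate.** Treatment restarts after
discontinuation (real year-5 any-HCQ proportions are therefore higher
than the generator's); calendar trends in GC duration (the generator's
year-5 any-GC is flat across cohorts — only the dose level trends);
in-hospital GC; biologics; regional or hospital-level clustering;
seasonality; coding errors beyond simple malformed ICD strings. Passing
tests therefore demonstrate that the algorithms recover known truths
under a plausible mechanism, not that the published estimates themselves
are reproduced.

## Simulation-study scales

The bootstrap-coverage study runs 100 replicates of a two-cohort design
(2005–2008 vs 2013–2016, 2,500 simulated persons per cohort), n_boot =
200, τ = 0.5, with unadjusted two-group designs — the generator draws
covariates independently of calendar cohort, so the cohort median shift
is the same estimand with or without adjustment. The true GC shift is the
configured −1000 mg; the true HCQ PDC shift has no closed form and is
computed once as the large-n limit of the same estimand on a 120,000
person draw at an independent seed. The oracle-equivalence suite checks
10,000 random dispensation streams against a day-by-day consumption
simulator, all two-sample splits with pooled n ≤ 12 against exact
enumeration, and intercept-only quantile fits against empirical quantiles
across the full τ grid.

## Known limitations

- Exposure begins at the first coded SLE visit; pre-diagnosis treatment
  is invisible, so cumulative doses are lower bounds.
- Dispensed is not consumed; PDC and cumulative dose are adherence-style
  proxies.
- The equivalence table and ATC lists are sensible defaults, not a
  validated study-specific supplement.
- The quantile-regression bootstrap reports percentile intervals only; no
  studentised or BCa variants.
- Average-daily-dose bins beyond the guideline-anchored 5 and 7.5 mg/day
  cut-points, and HCQ PDC bins beyond the 0.8 threshold, are conventions
  kept configurable.
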