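# sletrends

Register-based analysis of temporal trends in glucocorticoid (GC) and
hydroxychloroquine (HCQ) treatment during the first five years after an
incident diagnosis of systemic lupus erythematosus (SLE).

The package is written for pharmacoepidemiologists working with
Swedish-style register linkages — a population table, a care-visit table
(National Patient Register shape) and a pharmacy-dispensation table
(Prescribed Drug Register shape). Because individual-level register data
cannot be shared, the package ships a synthetic-register generator with
known ground truth, so the entire pipeline is testable end to end.

## What it computes

**Cohort.** Incident adult SLE: ≥2 visits coded ICD-10 M32.1/M32.8/M32.9
within 365 days, ≥1 at a specialist department; first SLE-coded visit
inside 2005-07-01 … 2021-09-01 (earlier coded care marks a prevalent case,
excluded); ≥2 years residency before diagnosis; age ≥18; ≥1 year of
follow-up. Covariates: calendar cohort of diagnosis (2005–2008 / 2009–2012
/ 2013–2016 / 2017–2021), age category, sex, education, birth region,
hospital type of the diagnosing visit, and hospitalised days /
specialist outpatient visits in the year before diagnosis.

**Exposures.** From dispensations, per yearly window *k* =
[dx+(k−1)·365.25, dx+k·365.25) and over the pooled 5-year window:

- any-use flags (≥1 dispensation of GC / HCQ / any immunosuppressant);
- cumulative GC dose in prednisolone-equivalent mg,
  Σ `n_DDD` × DDD<sub>mg</sub>(substance) × potency factor(substance);
- HCQ coverage: a 1-package dispensation covers 100 days, a multi-package
  dispensation 75 days/package; an early refill means the previous supply
  is treated as fully consumed (no stockpiling); coverage is truncated at
  end of follow-up. PDC = covered days / follow-up days in the window;
- average-daily-dose categories {0, (0,5], (5,7.5], >7.5} mg/day and the
  eight-way treatment-combination state.

**Trends.** Any-use by calendar cohort via adjusted logistic regression
(odds ratios vs 2005–2008, Wald 95% CI); group contrasts via a Wilcoxon
rank-sum test (midranks, exact enumeration for small samples); and
quantile regression of the 5-year cumulative GC dose and HCQ PDC across
τ = 0.10 … 0.90 (step 0.05), minimising the check loss
ρ<sub>τ</sub>(u) = u(τ − 1{u<0}) by linear programming, with 90% CIs from
a person-level percentile bootstrap.

## Worked example

```python
import pandas as pd
from sletrends import (SimulationConfig, simulate_registers, build_cohort,
                       summarize_exposures, wilcoxon_rank_sum)
from sletrends.analysis import gc_dose_trend

cfg = SimulationConfig(n_persons=4000, seed=11)
regs = simulate_registers(cfg)
cohort, exclusions = build_cohort(regs.persons, regs.visits)
exposures = summarize_exposures(cohort, regs.dispensations)

five = exposures[exposures.window == "cum"].merge(cohort, on="person_id")
five = five[(five.follow_up_years >= 5)
            & (five.diagnosis_date <= pd.Timestamp("2016-12-31"))]
gc = five[five.any_gc]
print(gc.groupby("calendar_cohort").gc_cum_dose_mg.median().round(0))

est = gc_dose_trend(cohort, exposures, tau_grid=[0.5], n_boot=200,
                    seed=0, adjusted=False)
print(est[est.term == "calendar_cohort[2013-2016]"]
      [["estimate", "se", "ci_low", "ci_high"]].round(0))
```

prints

```
calendar_cohort
2005-2008    7213.0
2009-2012    7522.0
2013-2016    6169.0
Name: gc_cum_dose_mg, dtype: float64
   estimate     se  ci_low  ci_high
1   -1050.0  471.0 -1747.0   -233.0
```

Of 3,384 case candidates, 2,996 form the incident cohort (183 prevalent,
64 residency, 63 age, 78 follow-up exclusions). Among patients treated
with GC at least once in their first five years, the median 5-year
cumulative prednisolone-equivalent dose falls from 7,213 mg (2005–2008
diagnoses) to 6,169 mg (2013–2016); the quantile-regression median shift
attributable to diagnosis period is −1,050 mg (90% bootstrap CI −1,747 to
−233) against a generator ground truth of −1,000 mg. The same pipeline
estimates the median 5-year HCQ PDC increase at 26.7 percentage points
(90% CI 15.7 to 34.9).

The same steps run from a shell:

```sh
sletrends simulate --n 4000 --seed 11 --out regs/
sletrends build-cohort --population regs/persons.csv --visits regs/visits.csv \
    --out cohort.csv --exclusions exclusions.csv
sletrends exposures --cohort cohort.csv --dispensations regs/dispensations.csv \
    --out exposures.csv
sletrends trends --cohort cohort.csv --exposures exposures.csv \
    --model gc_cum --out estimates.csv
sletrends report --cohort cohort.csv --exposures exposures.csv --out tables/
```

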