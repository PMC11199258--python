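# neoscr

Rescaled serum-creatinine (Pottel/Q-score) pharmacovigilance for extremely-low-birth-weight neonates.

## The problem

ELBW neonates (birth weight ≤ 1000 g) are at high risk of drug-induced acute
kidney injury, but the standard creatinine-based AKI definition — the
neonatal modified KDIGO rule, stage 1 = a rise of ≥ 0.3 mg/dL or ≥ 50%
versus the previous value — assumes a steady state.  ELBW creatinine is not
at steady state: it rises physiologically from birth to a peak on postnatal
days 3–4 and declines slowly afterwards, so the stage-1 thresholds are
crossed by healthy trajectories and the rule needs at least two measurements.

The alternative implemented here rescales each serum creatinine value by the
median creatinine of a day-specific reference population:

```
score(i, d) = Scr(i, d) / Q(d)
```

where `Q(d)` is the reference p50 serum creatinine (mg/dL) at postnatal day
`d` (day of birth = day 1).  In a healthy population the score is
distributed around 1 at every age, so a single observation can be read
bedside, and nephrotoxic-drug effects appear as upward shifts of the score.

## What the package does

- **`reference`** — load/validate/estimate/serialise day-specific p50 tables
  (estimation: per-day median of drug-free-day values, linear interpolation
  of sparse days).
- **`scoring`** — Pottel scores, drug-free-day identification (no
  ibuprofen/amikacin/vancomycin on the day before the measurement),
  drug-free-distribution summaries, explicit-threshold flagging.
- **`exposure`** — administration calendars, lag-1 exposure indicators,
  consecutive-treatment-day categories (0, 1, …, 5+), cohort exclusion rules
  (duplicates, death before day 7, admission on/after day 15, insufficient
  baseline) and the 28-day analysis window.
- **`staging`** — the neonatal modified-KDIGO stage-1 comparator and a 2×2
  concordance between the two detectors.
- **`models`** — the two linear mixed-model families, statsmodels-style
  (Model class → `fit()` → Results with `summary()`):

  Day-wise:  `score ~ 1 + log d + exposed + exposed·log d  (+ co-drug terms)`
  with patient-level random intercept and slope on `log d` (REML); the
  exposed-vs-unexposed difference at day *d* is
  `β_exposed + β_interaction · log d` with Wald CIs.

  Cumulative:  `score ~ 1 + log d + C(consecutive-days category)` with the
  same random structure; category means are contrasted against category 0.
- **`simulate`** — a seeded synthetic ELBW cohort generator with known
  ground truth (trajectory `Q(d)`, multiplicative patient variability, drug
  courses with saturating cumulative effects, irregular sampling, dropout),
  plus named recovery scenarios.
- **`cli`** — `neoscr simulate | build-ref | score | stage | analyze | recover`.

## Worked example

```python
import neoscr as ns

cohort = ns.simulate_cohort(ns.SimParams(seed=42))           # 201 patients
scored = ns.score_cohort(cohort.observations, cohort.reference_table, cohort.calendar)
print(ns.summarize_drug_free(scored))

model = ns.DaywiseExposureModel.from_scored(
    scored, cohort.calendar, ns.IBUPROFEN, adjust_for=ns.ANTIBIOTICS)
res = model.fit()
print(res.summary())
print(res.day_contrasts([4, 7, 10]).round(3))
```

prints (abridged):

```
{'n': 2426, 'mean': 0.974, 'sd': 0.258, 'skewness': 0.705, 'excess_kurtosis': 0.823}

Day-wise lag-1 exposure model: ibuprofen (adjusted for antibiotics)
===================================================================
n_obs: 3455   n_patients: 201   REML: True   random: intercept_slope
term                        coef        se        z           p     ci_lo     ci_hi
const                     0.9888    0.0168    58.69   2.23e-308    0.9558    1.0219
time                     -0.0071    0.0040    -1.79      0.0727   -0.0148    0.0007
exposed                  -0.0356    0.0317    -1.12       0.261   -0.0976    0.0265
exposed:time              0.0500    0.0186     2.69     0.00722    0.0135    0.0865

 day  mean_unexposed  mean_exposed   diff  ci_lo  ci_hi
   4           0.979         1.013  0.034  0.018  0.050
   7           0.975         1.037  0.062  0.046  0.078
  10           0.973         1.052  0.080  0.053  0.106
```

Reading: drug-free scores sit near 1 with SD ≈ 0.26, as they should after
rescaling; the ibuprofen × log-day interaction is positive, so the
exposed-vs-unexposed score difference grows with postnatal age —
≈ +0.03 at day 4 rising to ≈ +0.08 at day 10 in this simulated cohort,
recovering the saturating effect profile the generator injected.

The same pipeline runs from the shell:

```sh
neoscr simulate --n 201 --seed 42 --out cohort/
neoscr analyze --obs cohort/observations.csv --reference cohort/reference.csv \
    --exposures cohort/exposures.csv --demographics cohort/demographics.csv --out results/
```

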