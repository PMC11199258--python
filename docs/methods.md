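# Methods

## The rescaled-creatinine score

Serum creatinine (Scr, mg/dL) in extremely-low-birth-weight neonates follows
a strongly time-dependent physiologic trajectory: a rise from birth peaking
around postnatal days 3–4, then a slow decline.  The score used throughout
this package divides each measurement by the reference population's median
creatinine at the same postnatal day,

    score(i, d) = Scr(i, d) / Q(d),

with day of birth = day 1.  For a healthy reference population the score is
distributed around 1 at every day, which removes the trajectory and makes a
single observation interpretable.  The reference is day-specific only: the
sex split used by the original rescaling in older children is not applied to
neonates.  Scores are never clipped, winsorised or rounded, and a day outside
the reference table's coverage is an error, never an extrapolation.

Reference tables are either supplied (CSV `day,p50_scr_mg_dl`, contiguous
days) or estimated from a cohort: per-day median of values measured on
drug-free days, with days having fewer than `min_n_per_day` (default 5)
eligible values filled by linear interpolation between directly estimated
neighbours (nearest value at the ends) and flagged in the provenance log.
The bundled default curve used by the simulator is synthetic — a plausible
ELBW shape (≈0.59 mg/dL at day 1, peak 0.95 at day 3.5, ≈0.40 by day 28) —
and is not a published reference table.

## Exposure coding

Drug effects are expected with a one-day delay, so exposure enters the
models lagged: an observation on day *d* is exposed when the drug was
administered on day *d − 1*; day 1 has no prior day and is never exposed
(equivalently, always drug-free).  A "drug-free" day — used to calibrate the
score's null distribution and to select reference-estimation data — is one
with none of ibuprofen, amikacin or vancomycin given on the previous day;
same-day administration does not disqualify a day, implementing the lag rule
literally.

Cumulative exposure is the length of the uninterrupted run of administration
days ending on day *d − 1* (a one-day gap resets the count; administration on
or after the evaluation day does not count), reported in categories
0, 1, 2, 3, 4, 5+.

## The two mixed-model families

Both families model the score with patient-level random effects and are
estimated by REML (statsmodels `MixedLM`):

* **Day-wise**: fixed effects intercept, log *d*, exposure, exposure × log *d*
  (plus the same pair for an optional co-drug adjustment group); random
  intercept and random slope on log *d*.  The exposed-vs-unexposed mean
  difference at day *d* is β_exposure + β_interaction·log *d*; Wald (normal)
  CIs and p-values come from the fixed-effect covariance.  Predicted means
  fix the co-drug indicator at 0 and are reported only for days on which at
  least two exposed patients contribute.
* **Cumulative**: fixed effects intercept, log *d* and category dummies with
  category 0 as reference; the same random structure.  Category means are
  evaluated at the sample-average log day; each category is contrasted
  against category 0.  Categories with fewer than two observations are merged
  into the adjacent category (the top category merging downward) and logged.

The time variable enters the fixed and the random part on the same (log)
scale; mixing a log fixed trend with a linear random slope would make the
variance structure hard to interpret.  A linear-time variant exists solely
for AIC comparison of the transform (use maximum likelihood, not REML, when
comparing the two).  Two-sided α = 0.05 throughout; no multiplicity
correction; no small-sample degrees-of-freedom corrections
(Kenward–Roger/Satterthwaite are out of scope — with ~200 patients the
normal approximation is adequate, and the type-I harness checks it).

Numerical fallback: when the full random structure fails to converge or its
covariance is numerically singular (smallest eigenvalue ≤ 1e-8 of the
largest), the fit is retried with uncorrelated intercept/slope, then with a
random intercept only; every downgrade is recorded in `fit_info`.  Remaining
failure raises, with diagnostics.

Adjusted analyses include both drugs' lag indicators and interactions;
identical exposure columns raise a collinearity error naming the drugs, and
an adjustment group with no administrations reduces exactly to the
unadjusted fit.

## The modified-KDIGO comparator

Stage 1 flags a rise of ≥ 0.3 mg/dL or ≥ 50% versus the immediately
preceding measured value — exactly as the neonatal rule is worded, not a
48-hour window or lowest-prior baseline.  The first observation of a series
is never flagged.  Both thresholds use a 1e-9 absolute guard so that exact
decimal boundaries (0.50 → 0.80; 0.40 → 0.60) flag despite binary floating
point.  Because the rule compares raw consecutive values, the physiologic
day 1→4 rise can cross it; the detector-comparison tooling quantifies this
against score-threshold flags, whose threshold is always an explicit
parameter (the >2-years cut-off of 1.33 is not assumed to transfer; a
cohort-specific choice is drug-free mean + 1.96·SD).

## The synthetic cohort generator

Creatinine is generated as

    Scr(i, d) = Q(d) · exp(b0_i + b1_i·log d + ε − c(d)) · M(i, d)

with b0 ~ N(0, σ_b²), b1 ~ N(0, σ_s²), ε ~ N(0, σ_e²), and M the product of
the active drug multipliers for the consecutive-run categories ending on
day d − 1.  Defaults: σ_b = 0.22, σ_s = 0.05 (per log-day), σ_e = 0.10 —
chosen so the drug-free score SD is ≈ 0.26, the between/within split is
dominated by stable patient-level differences (maturational variability),
and the residual reflects assay plus day-to-day noise.

`c(d)` is a calibration offset.  Under the default `calibration="mean"` it
is half the total log-scale variance at day *d*, making the *expected*
drug-free score exactly 1.  Under `calibration="median"` it is 0, making the
*median* drug-free Scr exactly `Q(d)` — the natural target when validating
reference-centile estimation.  The two cannot hold simultaneously for
log-normal noise; the package exposes the switch rather than pretending
otherwise.  A consequence of the multiplicative model at SD ≈ 0.26 is a mild
right skew of the score (skewness ≈ 0.7–0.8); near-symmetry holds only in
the small-σ regime.

Cohort structure defaults mirror the motivating scale: 201 patients,
days 1–28, per-day sampling probability decreasing from 0.95 (week 1) to
0.40 (week 4) giving ≈ 3 200–3 400 observations; late death in 8.5% of
patients (day 7–28) truncating series.  Ibuprofen (PDA treatment): 62%
of patients, course start days 2–6, duration 1 + Poisson(2.2) (median 3,
capped 14).  Antibiotics: joint assignment 70.5% both / 5% amikacin-only /
5.5% vancomycin-only; a late-onset-sepsis episode start drawn within the
patient's stay from days 4–20, amikacin duration 1 + Poisson(5) (median ≈ 6),
vancomycin 1 + Poisson(6) (median ≈ 7); an optional short early-onset
amikacin course on days 1–3 in 25% of amikacin patients.

Drug effects are multiplicative on Scr (additive on the log score): each
consecutive-exposure category maps to a multiplier, e.g. the default
ibuprofen profile (1, 1.03, 1.058, 1.085, 1.10, 1.113) rises over the first
three exposure days then flattens; antibiotics are much smaller
(1 … 1.035).  At these effect sizes the multiplicative and additive-on-score
parameterisations differ by well under the recovery tolerances, since the
unexposed score mean is 1.

What the generator does **not** emulate: prolonged effects after drug
cessation, dose/level dependence, co-morbidity-driven confounding by
indication (except in the purpose-built confounded scenario), fluid-therapy
dilution effects, maternal-creatinine crossover in the first days, and
assay-specific rounding.  Passing recovery tests therefore demonstrates that
the estimation machinery recovers what this generative structure injects —
not that real ELBW data satisfy that structure.

## Simulation harnesses and problem sizes

The seeded harnesses (`neoscr.recovery`, also behind `neoscr recover`) fix
the day-wise evaluation day at postnatal day 5 — the day with the densest
lag-1 ibuprofen exposure under default course timing — chosen before any
harness was run.  Problem sizes are chosen so each experiment is decisively
powered while remaining desk-scale:

* type-I error: 100 null cohorts of 100 patients;
* constant-effect recovery (+0.10 on the score scale): 50 cohorts of 200;
* cumulative shape: 50 cohorts of 200, profile increments 0.10/0.08/0.06
  then 0.01/0.005 with lengthened courses (durations 4–8 days) so the upper
  categories are occupied — increments sized ≈3× the category-mean SE;
* confounding: 50 cohorts of 150; antibiotics act (×1.15) and enclose the
  inert ibuprofen course (start − 1 to end + 3) in 90% of ibuprofen-treated
  patients vs 15% antibiotic use otherwise, so the unadjusted ibuprofen
  contrast absorbs the antibiotic effect while the flanking antibiotic-only
  days and antibiotic-only patients identify the adjusted model;
* reference estimation: accuracy measured as per-day RMS relative error over
  5 replicate cohorts of 200 (a single cohort's error contains an
  irreducible ≈2% cohort-level component — the sample median of the
  patients' random intercepts — so replication measures the estimator, not
  one draw).

## Known limitations

* Wald inference can be mildly anticonservative in much smaller cohorts than
  the defaults; the type-I harness covers the default scale only.
* The cumulative model treats category membership as exogenous; in real data
  longer courses may follow sicker trajectories (confounding by severity).
* `build_reference` interpolates linearly and estimates no outer centiles;
  it is not a centile-regression substitute.
* The day-25 regime of antibiotic effects reported in exploratory analyses
  of real cohorts has no generator counterpart; the pipeline reports
  whatever the models estimate and offers no interpretation.
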