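# Methods

## Analysis model

The pipeline relates graphomotor/temporal features of digitally recorded
clock drawings to cognitive function in three covariate-adjusted stages.

**Feature scan.** Raw features are rank-inverse-normal transformed
column-wise: a value with tie-averaged rank *r* among *n* non-missing
values maps to Φ⁻¹((r − 3/8)/(n + 1/4)) (Blom offset; the prevailing
default in epidemiological applications — no other variant changes any
qualitative result, since the transform is monotone). Each transformed
feature `V_j` is then regressed against each of the 18 battery tests,
`test ~ 1 + V_j + age + sex`, by OLS with t-based two-sided p-values.
Rows with any missing value are dropped per model (complete-case,
never imputation), so the per-pair `n` varies with missingness.
Multiplicity is controlled per neuropsychological test at the Bonferroni
level α/n_features — the family is one test's scan over features, not
the features × tests grid. With α = .05, 105 features give 4.8×10⁻⁴ and
the 18-test battery gives 2.8×10⁻³.

**Composite scores.** For test *k* with *m* selected features,
`score_i = (1/m) Σ β_j V_ij`, the β_j being the scan effect sizes. The
1/m factor makes the composite a weighted *mean*; a plain-sum switch is
provided and inference is provably identical (rescaling a predictor by a
constant rescales its coefficient and SE by the inverse, leaving t and p
unchanged — asserted as a test). Participants missing any contributing
`V_ij` get a missing composite by default; an available-weight
renormalization is available but off, because silently changing the
weight vector per participant alters the estimand.

Selecting features and testing the composite on the same sample mirrors
the standard procedure and is the default. That reuse is
anti-conservative under the null (the composite is built from the
sample's most extreme statistics), which the test suite demonstrates by
simulation; a split-sample mode (selection on a random half, association
on the held-out half) is provided for honest inference.

**MCI models.** `logit(MCI) ~ 1 + predictor + age + sex + education`,
with sex coded female = 1 and education dummy-coded against a
no-high-school reference. Education enters only the MCI models. Wald
two-sided p-values, significance at 0.05/18.

## Statistical primitives

- OLS via least squares on the complete-case design; SEs from
  σ̂²(XᵀX)⁻¹ with σ̂² = RSS/(n − p). Rank deficiency raises an error
  naming the collinear columns. An exact fit (RSS ≤ 10⁻¹²·TSS) is
  reported with SE 0 and an `exact_fit` flag instead of NaNs.
- Logistic ML by iteratively reweighted least squares with step-halving;
  convergence when max|score| < 10⁻⁸ or the relative deviance change
  < 10⁻¹⁰ (at most 100 iterations). Wald SEs from the inverse observed
  information. Separation — diverging coefficients with saturated fitted
  probabilities — is flagged, the fit is reported as unconverged, and
  downstream tables refuse the row.
- Sparse education categories: a level with no outcome events (or no
  non-events) makes its dummy's MLE infinite regardless of the predictor
  of interest. With ~36 events over four levels an empty cell is a
  likely draw, so such levels are collapsed into the reference group
  before fitting, with a logged warning. This is the usual
  sparse-category handling in epidemiology and leaves predictor
  inference intact; the separation flag remains for predictor-driven
  separation.
- Logistic fits are refused outright below a configurable minimum of 10
  outcome events, where Wald inference is unreliable.
- Clock-face geometry uses the algebraic (Kåsa) least-squares circle:
  linear in (2x, 2y, 1), exact on points lying on a circle, including
  the three-point circumcircle; collinear input raises a
  degenerate-geometry error. Sub-micron residuals from chord
  discretization of sampled circles are expected and tolerated.

## Synthetic cohort generator

A single standard-normal latent cognition `g` drives everything, which
is the premise being rehearsed — shared cognitive variance between
drawing behavior and the battery.

- Covariates: age ~ N(62, 13²) years (clipped to 25–100), 51.6% women,
  education at proportions 11.1/18.7/26.7/43.4%. Latent
  `g = −0.35·z(age) + √(1−0.35²)·ε`, so cognition declines with age.
- Battery: `score = mean + ρ·SD·g + √(1−ρ²)·SD·ε` with loading ρ = 0.5,
  rounded to non-negative integers; Trail Making A/B are lognormal
  seconds matched to mean/SD 32 (17) and 88 (73) with a negative
  loading (worse cognition, longer times). Per-test missingness 1%,
  giving the per-model varying n. Default means/SDs are the emulated
  cohort's whole-sample values.
- MCI: the `round(prevalence·n)` lowest-`g` participants
  (prevalence 36/2062). The label is deterministic given `g`, which
  guarantees the expected directions (older, worse scores) at any
  sample size.
- Drawings: 15 strokes — a clock-face circle, twelve chevron number
  glyphs placed clockwise from 12, and hour/minute hands at ten past
  eleven (hour hand a sixth of the way from 11 to 12, minute hand at
  the 2 o'clock position). Kinematic links are exponential:
  radius 22.5·e^(0.08·g′) mm, pen speed 40·e^(0.15·g′) mm/s,
  inter-stroke pause 1200·e^(−0.30·g′′) ms, each with its own
  per-participant idiosyncratic component
  (`g′ = g + kinematic_noise_scale·ε_person`, default scale 1.0, so
  cognition explains about half of each log-kinematic parameter's
  variance). Without that person-level component the drawing features
  would order participants almost exactly by `g` and the deterministic
  MCI tail would be perfectly separable — stronger than any plausible
  real signal. Strokes are resampled at a constant pen speed on the
  80 Hz pen clock, with 0.15 mm Gaussian tremor per sample and
  lognormal (SD 0.15) pause jitter. The copy condition uses 0.6× pauses
  and 1.1× speed. Everything is reproducible from
  (config, seed, participant id, condition); pause jitter is drawn from
  its own stream with a fixed draw count, so kinematic comparisons
  across `g` at one seed are exact.

What the generator does **not** emulate: legible digits, stroke-level
handwriting style, hesitation loops, corrections and overdrawn strokes,
digital-clock-style drawings, pen pressure/hover, inter-feature
correlation beyond what `g` and the shared kinematic channels induce,
and any education or sex effect on cognition. Passing tests therefore
show that the statistical machinery behaves correctly under a known
latent-signal model — not that the feature registry would capture all
discriminative structure of real drawings.

## Units and conventions

Time in milliseconds from the first pen-down sample; coordinates in
millimeters, page convention (y down); speeds in mm/s; angles in
degrees clockwise from 12 o'clock. Command and copy conditions yield
separate feature columns (`_command`/`_copy`) and are scanned as
distinct features. Trail Making coefficients keep their natural sign
(positive = worse); no score is flipped.

## Problem sizes in the shipped checks

The test suite exercises the scan calibration at 50 features × n = 300
× 500 replicates, slope-recovery coverage at 1000 replicates of n = 120,
and byte-level pipeline determinism at n = 500 with both conditions; the
acceptance script runs the full pipeline at the study scale n = 2062 and
a 200-replicate null calibration. These sizes give binomial tolerances
of about ±2 percentage points on the calibrated rates.

## Known limitations

- The feature registry is a documented representative subset (~20 per
  condition) of the full production catalogs (100+ features), behind an
  extensible registry API; count-type features are constant on synthetic
  complete clocks and are automatically excluded from the scan.
- Strokes are taken as given (pen-down intervals with component
  labels); no re-segmentation or automatic component classification.
- Same-sample composite inference is reported because it mirrors the
  reference procedure; its p-values should be read descriptively (see
  the split-sample mode for confirmatory use).
- Cross-sectional only; no longitudinal structure or dementia-level
  outcomes.
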