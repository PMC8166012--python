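# Methods

This note documents the statistical procedures implemented in `spotna24`,
the assumptions behind the synthetic-cohort generator, the numerical
conventions, and the design choices made where the published methodology
left the design open.

## The estimation problem

Twenty-four-hour urinary sodium is the reference measure of dietary sodium
intake (roughly 90 % of intake is excreted in urine), but complete 24-h
collections are burdensome and error-prone at survey scale. Prediction
equations map a single spot-urine specimen plus demographics and
anthropometry to an estimate of 24-h excretion. `spotna24` implements the
direct-regression MyCoSS equation for Malaysian adults together with the two
comparators it was validated against: Tanaka (a sodium-to-creatinine ratio
method scaled by predicted 24-h creatinine) and INTERSALT (sex-specific
direct regression). All three are exposed with explicit unit contracts;
sodium conversions (1 mmol Na = 23 mg; 1 mg Na = 2.54/1000 g NaCl) and
creatinine conversions (molar mass 113.12 g/mol) are separate, exact steps —
no coefficient has a unit conversion folded into it.

## Synthetic cohorts

The participant-level survey data were never deposited, so the `cohort`
module generates records with the published marginal structure of the
analytic sample (n = 768). What it emulates, and how:

* **Demographics/anthropometry.** Sex (42.5 % male), age
  49.08 ± 15.1 y truncated to [18, 98] by resampling (not clipping, which
  would create point masses at the bounds), weight 66.60 ± 14.65 kg, height
  1.5794 ± 0.0874 m. Weight, height and sex are coupled through a Gaussian
  copula with declared default correlations (weight–height 0.4, male–height
  0.4, male–weight 0.2). Only marginals were published; the copula matrix is
  an assumption, configurable in `CohortParams`.
* **Urine chemistry.** Spot Na 2002.75 ± 1279.95 mg/L, spot K
  37.65 ± 32.27 mmol/L, spot Cr 96.34 ± 68.38 mg/dL, 24-h volume
  1563.53 ± 874.29 mL, 24-h creatinine 1.003 ± 0.439 g/day, 24-h potassium
  1078.89 ± 524.91 mg/day — all drawn from log-normal distributions
  moment-matched to the printed mean/SD, because concentrations are
  non-negative and right-skewed. A truncated-normal variant is available by
  flag (`urine_dist="truncated_normal"`); note truncation at zero lifts the
  realized mean above the nominal target (~8 % for spot Na), so the
  moment-match guarantee applies to the log-normal default only.
* **Outcome.** 24-h sodium is exactly linear-Gaussian:
  the published equation's coefficients applied to the covariates plus
  N(0, noise_sd²) noise. The rare negative draws (~1 %) are deliberately
  *not* truncated or resampled: conditioning the noise on the covariate-
  dependent mean would bias coefficient recovery (several SE at n = 5000,
  concentrated on the creatinine and weight terms). Non-negativity is
  guaranteed for concentrations, weights and volumes, not for the modelled
  outcome.
* **noise_sd = 1280 mg/day** is a one-time calibration (grid search at
  n = 100 000) chosen so that the fitted six-predictor equation correlates
  0.500 with the outcome, matching the published validation correlation
  (0.501); the implied raw spot-Na correlation is ≈ 0.24, inside the
  published neighbourhood (0.219).

What the generator does **not** emulate: survey weights and state-level
stratification, ethnicity effects, intra-subject diurnal variation in spot
sampling, correlated measurement error between spot and 24-h chemistry, and
the heteroscedastic, high-intake-underestimating residual structure visible
in real Bland–Altman plots. Passing tests therefore demonstrate correctness
of the *procedures* under a clean generating model, not field performance of
the equation on real populations.

## Screening

Eligibility: age ≥ 18, not pregnant, not fasting, no diagnosed kidney
disease, 24-h collection present. Completeness of the 24-h collection, in
evaluated order: volume ≥ 500 mL, duration ≥ 20 h, no missing void, and a
sex-specific daily-creatinine rule (6 mmol/day men, 4 mmol/day women;
g/day → mmol/day via the molar mass). Low daily creatinine indicates an
incomplete collection, so the default removes records *below* the threshold
(`exclude_below`); the inverted reading is selectable (`exclude_above`) for
audit, since published wordings of this rule vary. Spot urine is checked
only for presence and non-negativity. All failed rules are reported with
stable labels, screening is pure, and kept + excluded always partition the
input.

## Equation development

* **Stepwise OLS.** Candidates: male indicator, weight, height, age²
  (the final equation's age term is quadratic; linear age can be offered via
  `design_matrix`), spot Na, spot Cr, spot K. Entry at p < 0.05, removal at
  p > 0.10 — the classic SPSS-era convention; requiring removal > entry
  guarantees termination. p-values are two-sided t with n − p − 1 df.
  Standardized betas are recomputed as b·SD(x)/SD(y) (sample SDs), never
  copied from a published table.
* **Double cross-validation.** R[h,g] is the Pearson correlation, in
  evaluation group *h*, between the outcome and the composite
  Σ_j β_j(g)·z_j(h). Own-group z-standardization is the default; the
  `standardize="cross"` flag standardizes the evaluation group by the
  weight-source group's moments, which is algebraically identical to
  applying the other half's raw-coefficient equation. With own weights the
  composite correlation equals the half's multiple R exactly, and identical
  halves give shrinkage exactly zero.
* **Shrinkage gating.** Pooling is refused when either |R11²−R12²| or
  |R22²−R21²| exceeds 0.05 (configurable, overridable with `force=True`).
  0.05 is a pragmatic default for "small"; note that even for a perfectly
  stable model the expected shrinkage is positive and scales like
  2k(1−R²)/n (≈ 0.02 for k = 6, R = 0.5, n = 400 per half), so the gate
  will refuse a few percent of same-model splits at study scale — a
  property worth knowing before interpreting a refusal as instability.
* **Sample size.** Fisher-z: C = ½·ln((1+r)/(1−r)),
  n = ⌊((z₁₋α/₂ + z_power)/C)²⌋ + 3, the squared term truncated to an
  integer before adding 3 (matching the convention of common clinical
  sample-size software). At r = 0.15, α = 0.05, power 0.80 this gives 346
  per group.
* The pipeline runs stepwise selection in each half, cross-validates on the
  union of the two selections (a common predictor set is required for
  comparable composites), and refits stepwise on the pooled data for the
  final equation.

## Agreement validation

Bland–Altman on d = predicted − measured (direction fixed): mean bias,
SD of differences (n − 1 denominator, as everywhere in the package), limits
of agreement mean ± 1.96·SD, bias CI mean ± 1.96·SD/√n. The 1.96 normal
quantile is the default because the published intervals back-calculate to
it most closely; `ci_method="t"` substitutes the t(n−1) quantile for small
samples. The one-sample test of zero mean bias uses the same quantile
convention as the CI. Pearson correlations report two-sided t-based
p-values. The multi-equation comparison converts every estimator to mg/day,
drops records where an estimator is undefined (Tanaka requires spot Cr > 0
and predicted creatinine > 0) with the skip count reported, and orders rows
by |mean bias|.

## Numerical conventions and edge cases

* OLS is solved through statsmodels' QR-based fit; rank-deficient designs
  are rejected with the collinear columns named (pivoted-QR diagnosis), and
  constant columns are rejected before fitting.
* Tanaka's PRCr constant defaults to the canonical −2244.45; the variant
  −224.45 that appears in some secondary printings yields implausible
  predicted creatinine (a constant PRCr offset of exactly +2020) and is
  available only as an explicit `as_printed` audit option.
* Spot sodium below 400 mg/L triggers a unit-suspicion warning (plausibly
  an mmol/L entry), never an error; heights above 3 m are rejected at CSV
  read as cm entries.
* All randomness flows from a single `numpy.random.default_rng` seed;
  identical configuration and seed reproduce byte-identical output bundles,
  and every artifact carries the package version, seed and a hash of the
  analytic configuration (output paths excluded).

## Problem sizes used in the checks

The automated checks run at deliberately modest scale: marginal calibration
and coefficient recovery at n = 5000, generator correlation calibration at
n = 20 000, shrinkage behaviour over 100 independent 400-per-half splits
(plus 12 splits at 2000 per half for the large-n limit), and the end-to-end
pipeline at the study scale of 768. These sizes give Monte-Carlo error well
inside each asserted band while keeping a full run in seconds.

## Known limitations

* The generator's independence assumptions (spot measures mutually
  independent, independent of anthropometry) are simplifications; real spot
  concentrations share hydration-driven correlation. Consequently the
  synthetic Tanaka/INTERSALT biases differ in magnitude (though not in
  ordering) from the published ones.
* Shrinkage gating at 0.05 is a convention, not an inference; see above.
* Standardized betas published for the original equation are inconsistent
  with the printed unstandardized coefficients and SDs for some predictors
  (e.g. spot sodium); this package always recomputes them.
* No regularized regression, bootstrap CIs, or proportional-bias modelling
  of the Bland–Altman plot are provided.
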