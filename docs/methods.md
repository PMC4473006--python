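# Methods

## Case definition and cohort QC

Osteoporosis follows the WHO rule on the *lowest* of the three site
T-scores (lumbar spine, femoral neck, total hip): a woman is a case iff
min(T) ≤ −2.5, with the boundary inclusive. The QC disposition is a single
pass in a fixed order: males out, non-postmenopausal out, anyone missing a
T-score at any site out, then extreme values out — age, height, weight, or
menopause age deviating from the variable's mean by strictly more than
`sd_multiple` (default 3) SDs. The reference means/SDs are computed once,
per variable on complete cases, on the sample surviving the first three
steps, not re-estimated after each removal; they are recorded on the
returned cohort (`qc_moments`) so the pass can be replayed exactly, which
is what makes the operation idempotent. A missing menopause age exempts a
woman from that variable's rule only; tri-state questionnaire answers are
never coerced — "missing" stays missing throughout the package.

## The derivation pipeline

All regressions are ordinary least squares with the lowest-site T-score as
the response (configurable to a single site). Continuous predictors enter
per 10 units (years, cm, kg) so coefficients are comparable across
variables; binary factors enter as 0/1 with unanswered rows excluded from
that model's complete cases (no imputation, matching the per-question
denominators such data typically have). The univariate screen keeps
candidates with p < α (default 0.05); zero-variance candidates are skipped
with a warning.

**Integer weights.** Each multivariable beta is divided by a scale anchor
and rounded to the nearest integer, ties away from zero. The default
anchor is **half the largest |β|**, which pins the dominant variable (age
in this setting) at weight ∓2 and reproduces the published weight column
(−2, 1, 2, 1, −1, −2, −1) from the published betas. The alternative anchor
— the smallest |β| — also reproduces that column and is available as
`anchor="min_abs"`, but it is statistically fragile: the smallest
coefficient is the least precisely estimated, and under resampling at
n = 20,000 its sampling error alone flips the weight of body weight
between 2 and 3 in roughly a third of replicates. Since the package's
recovery guarantees are stated over repeated cohorts, the stable anchor is
the default. A weight that would round to 0 under the half-max anchor is
clamped to ±1 so every retained variable contributes.

**Item reduction.** Backward elimination on the integer index: at each
step every one-smaller model is refit (OLS on the survivors) and its
weights re-derived against the *frozen* full-model anchor, participants
are re-scored, and the variable whose removal costs the least AUC for the
case labels is dropped. Keeping the anchor frozen is deliberate: the
published two-variable index keeps the full-model weights (−2, +2) rather
than re-normalising, and re-anchoring per step would collapse any
two-variable model to (−1, +1). All candidate AUCs are evaluated on the
full model's complete-case rows so comparisons are paired. The default
stopping rule is **stepwise**: stop when the best single-step loss exceeds
`tol_auc` (default 0.01, the loss the original developers accepted when
going from seven variables, AUC 0.749, to two, AUC 0.739). A cumulative
rule (total loss versus the full model ≤ tol) is available via
`stop="full"`; on cohorts whose true cumulative seven-to-two loss sits
essentially at the tolerance, the cumulative rule is a coin flip about
where it stops, while the stepwise rule terminates at {age, weight}
reliably — which is why it is the default.

**Cutoff.** Every integer in the observed score range is evaluated with
positivity = score < cutoff; the cutoff maximising Youden's J is returned,
ties broken toward the larger (higher-sensitivity) cutoff. A near-flat J
profile (max J < 0.05) triggers a warning instead of an error.

## Evaluation

Lower score = more at risk, so ROC thresholds sweep "score < t" over every
observed value plus an all-positive sentinel. The trapezoidal AUC equals
the Mann–Whitney concordance probability with ties counted ½ (asserted to
1e-12 against an O(n²) oracle in the tests); for a binary rule the
two-segment ROC gives AUC = (sensitivity + specificity)/2 exactly.
Confidence intervals use the DeLong variance estimator (cross-checked
against pROC's `ci.auc` on a frozen fixture); Hanley–McNeil is available
as an option. Rule comparisons on the same cohort use the paired DeLong
covariance for the AUC difference and its z-test p-value (validated
against a score-swap permutation test). Metrics with a zero denominator
are reported as undefined, never as 0, and every proportion is carried
both as a float and as its exact count fraction so table-style one-decimal
percentages are bit-exact.

## The synthetic cohort generator

The generator's defaults emulate the OSTAi development cohort; they are
study conditions, not tuning knobs.

- **Demographics** — truncated (±4 SD) multivariate normal with means/SDs
  age 66.0/9.6 y, height 153.9/5.8 cm, weight 56.9/8.8 kg, menopause age
  49.3/4.5 y. The correlation matrix (age–height −0.30, age–weight −0.15,
  age–menopause +0.10, height–weight +0.40) reproduces the published
  univariate-versus-multivariable coefficient attenuation for the
  continuous variables (e.g. height 0.57 univariate vs 0.18 adjusted). In
  the joint-normal tail menopause age can exceed age (~5% of rows); it is
  clipped to age to keep the domain invariant.
- **Questionnaire factors** — Bernoulli with the study prevalences
  (previous fracture 15.0%, parent hip fracture 10.7%, smoking 1.3%,
  glucocorticoids 6.8%, rheumatoid arthritis 7.4%, secondary osteoporosis
  8.4%, alcohol 0.7%). Previous fracture, smoking, and glucocorticoid use
  depend on age (logistic in standardised age; yes-vs-no mean-age offsets
  +6.5/−1.8/−2.1 years) because age-independent binaries cannot reproduce
  the published attenuation (previous fracture −0.464 univariate vs −0.228
  adjusted); intercepts are solved numerically so the marginal prevalences
  stay at their configured values. Non-response is
  missing-completely-at-random, independently per question, at the
  observed response rates (64–72%).
- **T-scores** — each site is intercept + shared linear predictor (the
  published per-unit betas; factors null in the published screen get 0)
  + a shared per-woman "bone level" noise term (SD 0.74) + site noise
  (SD 0.91/0.59/0.59). The split matches the observed marginal T-score
  SDs (≈1.3/1.1/1.1) and gives a cross-site correlation of ≈0.6, typical
  of DXA sites. Base intercepts put the site means at −1.8/−1.8/−1.0, and
  a common shift is then calibrated by bisection so the realised
  lowest-site prevalence of T ≤ −2.5 hits the target 41.3%. The
  calibration sample (n = 200,000, drawn from a seed-derived child stream)
  is larger than the accuracy requirement (±0.5 pp at n = 100,000) to
  leave headroom for the check sample's own noise.
- **Determinism** — all draws use PCG64 seeded through
  `numpy.random.SeedSequence`; a (config, seed) pair reproduces the cohort
  byte-identically.

What passing tests on these cohorts shows: the pipeline recovers the
generating structure (it ends at {age, weight} with weights (−2, +2) in
≥ 90% of seeds at n = 20,000, with a two-variable AUC near 0.72) and the
evaluation machinery is numerically exact. What it does not show: the
generator is Gaussian and linear, with MCAR non-response and no site or
referral structure, so real-data features such as skewed weight
distributions, informative missingness, or device drift are untested here;
the published real-data AUCs (0.739 OSTAi, 0.618 NOF 2013) are properties
of the original cohort and are not reproduction targets — synthetic
replicates land near 0.71/0.60.

## Numerical choices and problem sizes

- Integer rounding is nearest-with-ties-away-from-zero everywhere
  (truncation, the original OSTA convention, is an option); raw scores are
  pre-rounded to 9 decimals before integer rounding so that exact .5 ties
  are stable against float summation order (index raws are multiples of
  0.02 in exact arithmetic).
- Multivariable fits require ≥ 10 complete rows per variable and reject
  rank-deficient designs, naming the collinear columns.
- The NOF 2013 mapping uses the fields actually collected: "high-risk
  medication" → glucocorticoids; "condition associated with bone loss" →
  rheumatoid arthritis or secondary osteoporosis; BMI < 18.5 needs height
  and weight, and is reported "not evaluable" (other criteria still
  checked) when they are absent. Smoking and alcohol are FRAX candidates
  but not NOF referral triggers.
- Test and acceptance runs use n = 2,000–20,000 cohorts (20 seeds at
  n = 20,000 for the recovery property; one n = 100,000 draw for the
  calibration check), sizes at which each derivation run takes well under
  a second while the recovery and calibration properties are already
  sharp.

## Known limitations

- The published NOF 2013 AUC (0.618) differs slightly from the binary-rule
  identity (0.783 + 0.467)/2 = 0.625; how the original ROC was constructed
  for a binary rule is not stated, so 0.618 is not treated as a target.
- Whether the published mean index of −1.82 refers to raw or rounded
  scores is ambiguous; the package reports both (`ostai_raw`,
  `ostai_value`).
- No fracture-outcome prediction, FRAX probability computation, T-score
  conversion from g/cm², or imputation of questionnaire answers.
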