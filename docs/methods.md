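# Methods

This note documents the statistical model behind `dropscore`, the design
choices that were genuinely open, the synthetic-data generator and what
passing tests on it do and do not demonstrate, and the package's numerical
conventions.

## Composite score

The composite risk score is a convex combination of four domain subscores,
each on a 0–100 scale, with weights α = 0.40 (patient), β = 0.25 (donor),
γ = 0.20 (surgical), δ = 0.15 (center). Weights must sum to 1 within 1e-9;
because the combination is convex, the composite always lies between the
smallest and largest subscore and is strictly increasing in any subscore
with positive weight.

**Point tables.** Each subscore is an additive point table over the
domain's risk factors, normalized so that a zero-risk profile maps to
exactly 0 and the worst configured level of every factor maps to exactly
100. Point contributions are non-negative by schema, which guarantees the
monotonicity property "adding a risk factor never lowers the subscore."
The shipped defaults encode the direction and approximate ordering of the
published univariate prognostic evidence for DMEK: diabetes (20 points) and
hypertension (16) are the largest patient contributions, followed by a PBK
(pseudophakic bullous keratopathy) diagnosis (14) versus FECD (0); donor
quality is dominated by endothelial cell density bands (40 of 100 points);
surgical complexity by surgeon-experience and unfolding-time bands (30
each). The exact values are package choices, versioned in
`dropscore.config.DEFAULT_POINT_TABLES` and fully overridable through the
JSON config; they are *not* estimates fitted to data.

**Missing data.** A missing factor contributes exactly half of its maximum
points; a domain in which every factor is missing therefore scores exactly
50.0 and is flagged `defaulted`. This mirrors the common clinical situation
in which eye-bank or center records are unavailable and keeps the composite
computable for every row.

**Categories.** Printed category bins (0–25, 26–50, 51–75, 76–100) are
interpreted as half-open real intervals [0, 26), [26, 51), [51, 76),
[76, 100] so that every continuous score has a unique category and a score
of 26.0 is Moderate. Scores are carried at full precision; reports round to
one decimal.

**Weight sensitivity.** `weight_sensitivity` re-scores a cohort under
alternative weight vectors and reports mean, SD, the share of eyes at High
risk or above, and the fraction whose category changes versus baseline. The
three standard scenarios are the original weights, equal weights (0.25 × 4),
and a patient-dominant scenario (α = 0.60 with the remaining 0.40 split
proportionally to the baseline ratios 0.25 : 0.20 : 0.15). On the default
seeded cohort, 10.6% of eyes change category under equal weights and 14.0%
under the patient-dominant scenario — more than in a narrow single-center
case mix, because the synthetic cohort is deliberately spread across all
four categories and more eyes sit near boundaries.

## Outcome models

All times are months. Default coefficients are calibration targets chosen
to reproduce published aggregate 12-month benchmarks, not fitted estimates
(no fitted coefficients are available, and a cohort without failure events
cannot identify a survival model).

* **Graft survival.** Proportional hazards with an exponential baseline:
  `S(t) = exp(−h₀t)^exp(β₁(s − 50))`. The reference score is the scale
  midpoint 50; `h₀ = −ln(0.935)/12 ≈ 0.0056` per month is pinned so the
  reference eye has 93.5% 12-month survival. A single-rate exponential
  cannot simultaneously match 12-month and multi-year survival anchors
  (it implies 81.7% at 36 months); the 12-month anchor was chosen because
  it is the best-supported one. β₁ defaults to 0.055 per score unit (see
  calibration below).
* **Visual acuity.** Linear in the score, preoperative BCVA and a PBK
  indicator, in logMAR units (lower is better):
  intercept −0.077, slopes 0.0035 / 0.05 / 0.04. At the synthetic cohort
  mean this yields ≈ 0.15 logMAR at 12 months.
* **Endothelial cell density.** `ECD(t) = ECD₀·e^(−λt)` with
  `λ = λ₀(1 + 0.3(s − 50)/50)`, λ₀ = 0.032/month, floored at zero, and a
  diagnosis multiplier of 1.5 (configurable 1.4–1.6) for PBK eyes, whose
  compromised microenvironment roughly doubles the decay rate relative to
  FECD-predominant series. `back_calculate_lambda` inverts the decay law
  (`ln(ECD₀/ECD_t)/t`) and round-trips with `predict_ecd` to 1e-10; rising
  densities are rejected as out of model scope rather than returned as
  negative rates.
* **Complications.** Logistic models per named complication. Defaults:
  slope 0.060 (rebubbling) and 0.055 (rejection) per score unit, intercepts
  anchored so the cohort-level rates at the synthetic mean score (~42) are
  25.3% and 7.2%.

**Calibration rationale.** The published synthetic-validation description
is internally over-determined: the reported category shares
(21.4/48.6/24.2/5.8%) together with mean 42.3 imply a wider, right-skewed
score distribution than the reported SD of 15.7, and the reported
discrimination (AUC 0.782 for graft failure) implies a steeper score–hazard
slope than the reported per-category failure rates. The package resolves
this by (i) matching the category shares and AUCs, which the validation
battery actually exercises, and (ii) treating the per-category outcome
cells, SD and correlation coefficients as directional anchors only. With
the defaults above, a 20 000-eye cohort gives shares 21.0/51.9/21.8/5.4%,
graft-failure AUC ≈ 0.78, rebubbling AUC ≈ 0.76 and rejection AUC ≈ 0.77.

## Synthetic cohort generator

The generator's job is to emulate a heterogeneous multicenter DMEK case mix
with known ground truth, not any particular registry.

* **Latent structure.** Each of the 19 risk factors has a standardized
  latent variable `Zᵢ = lᵢG + √(1 − lᵢ²)eᵢ`. `G` is a shared
  "case severity" factor — a standardized log-normal with log-scale sigma
  0.5, giving the right-skewed tail a heterogeneous case mix shows (a
  minority of eyes accumulate many risk factors at once). Loadings default
  to 0.38–0.68 (0 for triple-DMEK, which is not severity-driven) and
  produce subscore intercorrelations of roughly 0.2–0.45. Residuals are
  Gaussian; explicit pairwise latent correlations can be layered on top
  (the matrix is eigenvalue-clipped back to positive definite if needed).
* **Marginals.** Flags and ordinal grades are thresholded at exact
  quantiles of the latent mixture distribution (computed by Gauss–Hermite
  quadrature, 80 nodes), so configured prevalences are hit exactly in
  expectation even with a skewed factor. Continuous factors map linearly
  (normal) or exponentially (log-normal) from the latent and are clipped to
  physical ranges. Defaults: 50% PBK, 35% diabetes, 50% hypertension,
  donor ECD ~N(2580, 300) clipped at the 2300 transplantability floor,
  median surgeon experience ≈ 100 cases, median unfolding ≈ 9.5 min,
  median center volume ≈ 27 cases/year. PBK eyes are pseudophakic by
  definition; FECD eyes split 58/40/2% phakic/pseudophakic/aphakic.
* **Outcomes.** Generated from exactly the outcome models above: failure
  times are exponential with the model hazard (1- and 3-year indicators are
  thresholds of one time), rebubbling/rejection are Bernoulli draws of the
  logistic probabilities, BCVA adds N(0, 0.15²) logMAR noise (floored at
  0), and 12-month ECD multiplies the decay prediction by mean-one
  log-normal noise (sigma 0.12) so densities stay positive.
  `link_strength_scale = 0` removes the score–outcome association while
  preserving marginal rates, providing a null for type-I-error checks.
* **Determinism.** One integer seed drives a `numpy` `SeedSequence`;
  profile generation and outcome simulation use separately spawned child
  streams. Identical (config, seed) reproduce a cohort byte-for-byte.

**What the generator does not emulate.** Real registries have informative
missingness, center-level clustering beyond a volume band, measurement
error in ECD imaging, competing risks, and non-proportional hazards. A
validation statistic passing on this generator demonstrates that the
statistic and the scoring pipeline are implemented correctly and that the
score recovers a signal it genuinely contains — not that the score is
clinically valid, which requires prospective multicenter data.

## Validation statistics

* **DeLong AUC.** Mann–Whitney estimate with ties counted ½, variance from
  midrank structural components; the default CI is Wald on the AUC scale
  truncated to [0, 1] (logit-scale CI via `ci_scale="logit"`). Equals
  exhaustive pair counting exactly (tested to 1e-12).
* **Hosmer–Lemeshow.** Quantile groups of predicted probability (default
  10; the group count is a parameter because published analyses vary),
  χ² = Σ(O−E)²/(E(1−E/n_g)), df = groups − 2. With externally supplied
  (unfitted) probabilities this df convention is mildly anti-conservative;
  empirically the rejection rate at the 5% level is ≈ 5% under a correctly
  specified generator.
* **Calibration line.** Slope = coefficient of logit(p) in a refit
  logistic model; calibration-in-the-large = intercept of an offset
  logistic model with slope pinned at 1. Negative intercept means
  predictions are systematically too high.
* **Decision curves.** Net benefit TP/n − FP/n·t/(1−t) classifying
  positive at p ≥ t, with treat-all and treat-none (≡ 0) references.
* **2×2 tables.** OR = ad/bc with a flagged Haldane–Anscombe 0.5
  correction when a cell is zero; Woolf logit CI; two-sided Fisher exact p
  as the sum of hypergeometric outcomes no more probable than the observed
  table. Because the CI method is a convention choice, published CIs are
  not used as test anchors.
* **Logistic fitting.** IRLS maximum likelihood (statsmodels GLM,
  parameter tolerance 1e-10); (quasi-)separation raises an explicit error
  rather than returning divergent coefficients. Score equations
  Σ(yᵢ−p̂ᵢ)xᵢⱼ = 0 hold within 1e-6 at convergence. Backward stepwise
  selection (entry p < 0.10, removal p > 0.15) ships as an explicitly
  discouraged legacy utility.
* **Model comparison.** LR = 2ΔlogL with an upper-tail χ² p; AIC = 2k −
  2logL; Brier score = mean squared probability error.

## Numerical conventions and edge cases

Scores are clipped to [0, 100] only against float drift at the ceiling;
out-of-range inputs raise instead of clipping. Category thresholds use
`searchsorted(side="right")`, so boundary scores go to the higher category
deterministically. Empty cohorts, single-class outcomes, degenerate
probabilities (0 or 1) and negative times/densities raise typed exceptions
(`ValidationError`, `ConfigurationError`, `SeparationError`,
`DiscriminationUndefinedError`) — the CLI fails closed, writing no partial
output. JSON reports serialize with sorted keys and full float precision,
so write–read round trips are bit-identical.

## Test problem sizes

The suite exercises the simulator at n = 500 (the standard validation
cohort size, seed 42), n = 5 000 for discrimination/calibration, n = 10 000
for marginal-frequency checks and n = 50 000 for law-of-large-numbers
checks; parameter recovery uses 100 replicates of n = 1 000 and the
type-I-error study 1 000 replicates of n = 76 (the clinical sample size).
These sizes keep every statistical tolerance at ≥ 3 standard errors while
the whole suite runs in well under a minute of simulation time.

## Known limitations

* Default point values and outcome coefficients are literature-anchored
  design choices, not estimates; any quantitative claim about real DMEK
  cohorts requires refitting.
* The exponential baseline hazard cannot represent the empirically
  decelerating failure rate beyond the first year.
* Observed per-category event rates on a single 500-eye cohort are noisy:
  with a ~1% failure probability in the Low bin (~95 eyes), a strictly
  monotone observed gradient across all four categories has only ≈ 90%
  probability per seed even though the generating probabilities are
  strictly monotone by construction.
* The decay model is single-exponential; published kinetics suggest a
  biexponential with early-phase half-time ≈ 3 months, which the λ
  convention here averages over the first year.
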