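# Methods

## Scope and data model

The package scores and validates ambulatory **lung-cancer** cohorts
only: the Khorana site item is hard-coded to 1 point, which avoids
importing the full multi-tumor site taxonomy and matches the population
the scores are validated on here. COMPASS-CAT is implemented with the
eight items listed in the README; items of the original model that do
not apply to this population (hormonal therapy, breast-cancer-specific
items) are deliberately not implemented.

A patient record carries the raw inputs the scores need; three composite
fields are *derived*, never stored: advanced disease (TNM 7th-edition
stage IIIB or IV), the cardiovascular composite (≥ 2 of its seven
predictor flags), and the risk band of each score. `bmi_ge_35` and
`obesity` both encode BMI ≥ 35 kg/m² — one plays the body-habitus role
in the Khorana family, the other the cardiovascular-predictor role in
COMPASS-CAT — and validation enforces their agreement. Mandatory fields
may not be missing; a row with a missing mandatory field is rejected
with a diagnostic naming the patient and field, because silent
imputation would corrupt score counts. Comorbidity indices (Charlson,
simplified comorbidity score) and anticoagulation details are treated as
pre-computed input flags, outside this package's scope, as are
Kaplan–Meier survival estimation and normality testing.

## Threshold conventions

Score items are exact at their boundaries and the strictness differs by
model, so it is pinned in tests:

| item | comparison |
|---|---|
| KRS-family platelets | strictly > 350×10⁹/L |
| KRS-family leukocytes | strictly > 11×10⁹/L |
| KRS-family hemoglobin | strictly < 10 g/dL (or ESA use) |
| BMI item | ≥ 35 kg/m² |
| COMPASS-CAT platelets | ≥ 350×10⁹/L |
| COMPASS-CAT time since diagnosis | ≤ 6 months |

Risk bands: KRS 0 low / 1–2 intermediate / ≥ 3 high (the original
three-band convention; the site point makes 0 unreachable for lung
cancer, so low is never emitted in practice). PROTECHT and CONKO publish
only the ≥ 3 high threshold; sub-threshold patients are labelled
intermediate and low is never emitted. COMPASS-CAT is two-band, high at
≥ 7.

## Statistical procedures

* **Diagnostic metrics.** sensitivity = tp/(tp+fn), specificity =
  tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn), each with an exact
  Clopper–Pearson 95% interval. A zero denominator yields an explicitly
  flagged undefined metric, never a silent 0. Printed percentages round
  half away from zero (82.5 → 83), the convention of clinical tables;
  stored values keep full precision.
* **Odds ratios.** Cross-product OR = ad/bc with the Woolf logit
  interval, SE = √(1/a+1/b+1/c+1/d). This, not an iterative fit, is the
  univariate-screen estimator — for a single binary factor the logistic
  MLE coincides anyway, and the suite asserts the identity to 6
  significant digits. Any zero cell triggers the Haldane–Anscombe +0.5
  correction on all four cells, flagged in the result. A double-zero
  diagonal or a constant margin is non-estimable and flagged.
* **Chi-square.** Pearson X², 1 df, no Yates correction — validated by
  reproducing reference p-values 0.0002 and 0.0122 from their printed
  counts.
* **Mann–Whitney U.** Midrank tie handling. Both samples ≤ 8: exact
  two-sided p by enumeration of all group assignments of the pooled
  values (the asymptotic path cannot be trusted there, and scipy's exact
  method declines ties). Larger samples: normal approximation with tie
  correction, no continuity correction. All pooled values identical:
  degenerate, p = 1.
* **ROC.** One threshold per distinct score, descending, with a +inf
  sentinel so the curve starts at (0,0); test-positive means score ≥
  threshold. AUC by trapezoid — identical to the Mann–Whitney
  concordance with ties counted ½ (property-tested), i.e. the C
  statistic. SE by Hanley–McNeil with a normal 95% interval (clipped to
  [0,1]). Optimal cutoff maximizes Youden J = sensitivity +
  specificity − 1; the published study this pipeline mirrors reports a
  cutoff without naming a criterion, so Youden is adopted as the
  standard default, with ties broken toward the higher threshold (fewer
  test-positives).
* **Logistic regression.** statsmodels `Logit` maximum likelihood
  (Newton, tolerance 1e-10, ≤ 100 iterations) behind the package's fit
  surface; Wald SEs from the inverse observed information; OR = exp(β)
  with exp(β ± 1.96·SE) intervals. A singular information matrix — the
  signature of separation — falls back to BFGS, and a fit with any
  fitted probability within 1e-6 of 0/1 together with |β| > 10 is
  flagged `separation_detected` with a warning; coefficients are
  reported but not trusted, and no penalized repair (Firth, Bayes) is
  attempted.
* **Screen → multivariate.** Factors enter the multivariate model when
  their univariate χ² p < `alpha_in` (default 0.01, the reference
  study's rule). Non-estimable factors and factors with a zero cell
  against the outcome (which would induce quasi-complete separation, as
  a hospitalization flag present in 100% of events does) are excluded
  and logged. No multiple-testing correction is applied, matching the
  validated procedure.

## Synthetic cohort generator

The generator emulates a single-center ambulatory lung-cancer cohort of
the size and composition of the 118-patient reference population.

* **Marginals.** Covariates are drawn independently from configured
  prevalences; the defaults are the reference counts over 118 (male
  68/118, atrial fibrillation 13/118, chronic kidney disease 15/118,
  platinum 96/118, gemcitabine 25/118, recent hospitalization 66/118,
  …). Anthracycline and ESA use default to 0 (not administered in the
  reference setting). Peripheral artery disease has no reference count;
  8% was chosen once as realistic for a heavy-smoker oncology
  population. The hemoglobin < 10 g/dL prevalence uses the reference
  *count* 4/118 (its printed percentage is a typographical slip).
* **Couplings.** Only three departures from independence: TNM stage is
  drawn categorically from the reference stage distribution and
  advanced disease is derived from it, not drawn (the derived
  prevalence is ~74%, the stage rows' own total, which the reference
  table's separately printed 64% contradicts — the stage rows are
  honored); blood counts are drawn continuously (platelets and
  leukocytes log-normal with σ = 0.35 / 0.30, hemoglobin normal with
  σ = 1.6 g/dL) with location solved so the threshold-crossing
  probability matches the configured prevalence; and obesity ≡
  bmi_ge_35. Independence elsewhere is a deliberate simplification —
  only marginals are known, no joint distribution — so synthetic
  correlations (and the synthetic prevalence of a high COMPASS-CAT
  score, ~80% vs the reference 71%) must not be over-interpreted, and
  passing tests on synthetic data show pipeline correctness, not
  clinical transportability.
* **Outcome model.** VTE ~ Bernoulli(expit(β₀ + Σ ln(OR_f)·1[f])) with
  default active factors high COMPASS-CAT score (OR 8.73, computed from
  the patient's own generated covariates via the score itself),
  gemcitabine chemotherapy (OR 3.37) and atrial fibrillation (OR 7.19).
  β₀ is calibrated so the expected event rate equals the target
  (default 20/118 = 16.9%): closed form logit(target) − offset when the
  linear-predictor offset is constant across patients, otherwise
  bisection of the mean fitted probability over a 200,000-patient
  Monte-Carlo covariate sample drawn from a fixed internal seed
  (monotone in β₀; interval shrunk to 1e-12, far below the 1e-4 rate
  tolerance). Calibration results are memoized per configuration.
* **Ancillaries.** Time since diagnosis uniform on (0, 12] months
  (newly diagnosed patients; ~half fire the ≤ 6-month item), follow-up
  uniform on [1, 24] months, VTE event time exponential with median
  2.5 months truncated at follow-up, death an independent 64% flag.
  These are plumbing for the record format, not analysis surfaces.
* **Reproducibility.** One `numpy.random.default_rng(seed)` stream
  drives every draw; the per-field draw order is documented in the
  module and is part of the contract, so a config + seed pair is
  bit-reproducible.

## Problem sizes and numerical choices

The test suite exercises exhaustive enumeration oracles for all four
scores (2⁴–2⁸ item combinations), exact identities on published count
tables, and stochastic checks at the sizes where they are sharp:
marginal fidelity and intercept calibration at n = 100,000 (±0.005
absolute on prevalences), and parameter recovery of the three
generating log-odds-ratios within ±0.1 from a single n = 100,000
cohort. The acceptance script uses the same n = 100,000 cohort for its
recovery quantities. Quantities that require the reference study's
unpublished patient-level scores (its AUC of 0.891, its 11-point
cutoff, its multivariate intervals) cannot be recomputed from printed
numbers; the suite substitutes the corresponding internal-consistency
properties (AUC ≡ concordance, MLE ≡ closed-form 2×2 OR, known-truth
recovery from the synthetic model).

## Known limitations

* No survival analysis (Kaplan–Meier, log-rank) and no competing-risk
  or anticoagulation-effect modelling.
* Separation is detected and reported, not repaired.
* The generator's covariate independence understates real-world
  clustering of cardiovascular comorbidities; joint (copula) modelling
  is out of scope.
* Scores other than the four implemented (Vienna CATS, ONKOTEV,
  Tic-Onco) and biomarker extensions (D-dimer, soluble P-selectin) are
  out of scope.
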