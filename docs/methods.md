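# Methods

`pedtriage` implements the model-development workflow behind a pediatric
emergency-department triage score: from a patient-level cohort it derives a
composite admission outcome, preprocesses the candidate predictors, selects
a stable predictor subset by bootstrap-stepwise AIC consensus, fits and
evaluates a logistic risk model, and stratifies patients into three triage
categories at dual risk thresholds. Because the derivation cohort is not
publicly downloadable, the package ships a synthetic-cohort generator with
known ground truth, which is what every statistical test and the acceptance
script run against.

## The model

Admission risk for one triage encounter is a logistic regression

    logit(p) = b0 + b1*sqrt(age) + b2*HR + b3*T + b4*MUAC + b5*VS(SpO2)
             + b6*concern + b7*breathing + b8*oedema + b9*pallor

with age in **months** under the square root, heart rate in bpm, axillary
temperature in °C, mid-upper arm circumference in mm, and SpO2 re-expressed
as a virtual shunt,

    VS(SpO2) = 70.103 * log10(101.687 - SpO2) - 55.833,

the equivalent intrapulmonary shunt fraction under an altitude-adaptive
physiological model. VS is strictly decreasing and linearizes the
relationship between saturation and gas-exchange impairment on the logit
scale, which is why its coefficient is positive while SpO2's marginal effect
on risk is negative. The published nine-predictor model is frozen in
`pedtriage.model.PUBLISHED_MODEL` and is never re-estimated; the scoring
module applies it with the dual thresholds 0.08 and 0.40.

One printed-rounding quirk is handled explicitly: the three-decimal oedema
coefficient 1.814 exponentiates to 6.13, while the published odds-ratio
column prints 6.14 (computed before rounding the coefficient). Tests assert
the other eight odds ratios exactly to two decimals and the oedema odds
ratio to within 0.01.

## Composite outcome

A positive outcome is an admission lasting at least 24 h, or a readmission
to any facility within 48 h of being sent home. The `>= 24 h` convention is
operative (a strict `> 24 h` flag exists), and a robustness variant counts
admissions of any duration. The variant's positive set is a superset of the
default's, which is asserted as a property test.

## Preprocessing

Missingness is assumed small (<5%) and completely at random; continuous
predictors are imputed with the column median, categorical/binary ones with
the column mode (ties toward the smaller value, deterministically).
Imputation statistics are computed on the full table by default, mirroring
a develop-then-validate workflow where imputation precedes splitting; pass
fold slices to `impute` for leakage-free variants. Disposition fields are
never imputed.

The events-per-variable screen drops a binary candidate when fewer than 10
outcome-positive rows carry it. The event count for a *binary* predictor is
defined as positives among carriers; continuous predictors have no
analogous per-level count and are exempt. Both choices are recorded in the
exclusion log.

## Variable selection

Stepwise AIC search starts from the intercept-only model and at each step
makes the single addition or removal that lowers AIC most; ties prefer the
smaller model, then the lexicographically smaller set, so the search is
deterministic given the data. The search is repeated on bootstrap resamples
of the cohort (default B = 2000; reduced sizes are used in tests for
runtime) and the consensus model keeps predictors present in at least 80%
of converged replicate models. Replicates whose resample contains one
outcome class are skipped and counted; inclusion frequencies use converged
replicates as denominator. A per-replicate seed sequence spawned from one
master seed makes the whole run reproducible.

All logistic fits go through `statsmodels` (Newton). Under separation the
MLE diverges; inside the stepwise loop a failed fit is replaced by a
small-ridge penalized fit whose deviance-based AIC proxy keeps a perfectly
predictive candidate eligible, and the final consensus fit falls back to
the same ridge (flagged in the model notes, standard errors withheld).
Stepwise agrees exactly with exhaustive best-subset AIC on instances with
up to five candidates, which is the test oracle.

## Evaluation

Discrimination is the rank (Mann-Whitney, ties one half) AUROC of pooled
out-of-fold predictions from stratified 10-fold cross-validation. The
"80:20 split with 10-fold cross-validation" wording of the original
workflow is ambiguous; the primary mode here is pooled out-of-fold 10-fold
CV, with a repeated stratified 80/20 Monte-Carlo holdout as a secondary
mode (`holdout_auroc`). Threshold metrics and the AUROC get percentile
bootstrap 95% confidence intervals (default B = 2000), matching the
asymmetric style of printed intervals; resamples on which a metric is
undefined are skipped and counted.

Calibration uses ten equal-count risk bins (duplicate quantile edges are
merged and noted), a logistic recalibration fit of the outcome on
logit(risk) whose slope/intercept summarize calibration (1/0 is perfect),
and a bootstrap bias correction: the recalibration map is refit on each
resample, evaluated at the original bin means, and the average optimism of
the refitted map is subtracted from the observed bin frequencies (default
B = 1000).

## Risk stratification

Candidate boundaries are the sorted unique predicted risks, with
test-positive meaning `risk > t`. The low threshold is the largest
candidate keeping sensitivity >= 90% (maximizing specificity subject to the
sensitivity floor); the high threshold is the smallest candidate reaching
90% specificity. Categories are inclusive on the left: risk <= low is
non-urgent, risk <= high priority, else emergency. If the thresholds cross
(e.g. perfectly separated risks) a degenerate two-category report is
produced with a warning rather than an error. Boundary metrics are computed
at the boundaries themselves from explicit confusion counts (reported as
TP:FP pairs); the original table's practice of evaluating metrics at the
upper/median/lower point of each category's risk range is deliberately not
reproduced. Degenerate target pairs outside (0, 1) are rejected as
configuration errors rather than silently falling back.

## Synthetic cohort generator

The generator defines the study conditions and is fixed, not tuned:

- **Size and outcome**: default n = 1612 with a target marginal event rate
  of 22.6%. The intercept offset that achieves the target is solved by
  bisection on the mean latent probability over the generated predictors.
  With the default marginals the published intercept already yields ~22%,
  so the solved offset is near zero.
- **Age**: a band mixture (<1 mo 5.0%, 1-12 mo 39.3%, 12-24 mo 25.2%,
  24-60 mo 19.7%, 60-120 mo 8.9%, >=120 mo 1.9%; uniform within band),
  ~89% under five years.
- **Vitals/anthropometry**: age-conditional normal draws centered on
  pediatric reference ranges shifted toward acute illness (e.g. heart rate
  145±22 bpm under 1 y, 125±20 at 1-5 y, 105±17 above; temperature
  37.6±1.0 °C; MUAC 132-170 mm by age). SpO2 is left-skewed:
  100 − Gamma(1.4, 2.2), floored at 50, giving ~2% of readings below 90%.
- **Symptoms**: parent concern 0.25, difficulty breathing 0.20, oedema
  0.02, pallor 0.08 — nuisance prevalences for pipeline testing, not claims
  about any real cohort. Decoy `noise_k` predictors are independent
  Bernoulli(0.2).
- **Internal consistency**: the latent Bernoulli draw from the true model's
  probability *is* the composite outcome; disposition fields are realized
  to agree with it (positives are mostly admissions >= 24 h, a 5% fraction
  are early readmissions; ~10% of all admitted stays are short stays
  attached to negative rows; early readmission occurs in ~1.5% of the
  non-admitted). Re-deriving the outcome therefore recovers the latent
  draw exactly, with no outcome misclassification — this is what makes the
  ±10% coefficient-recovery check at n = 50 000 a clean test of the fitting
  stack rather than of an attenuation artifact.
- **Missingness**: 2% per predictor column, completely at random, applied
  after outcome generation.

What the generator does **not** emulate: the correlation structure of real
vitals (draws are conditionally independent given age), seasonal and
site effects, the full 60-odd-variable candidate list, mortality (too rare
to model meaningfully), or measurement error in disposition records.
Passing tests therefore demonstrate that the pipeline recovers known
structure under its own assumptions — not that the published model is
correct for any particular population.

## Numerical choices and problem sizes

- Logistic fits: Newton with a 100-iteration cap; non-convergence or
  non-finite parameters triggers the ridge fallback (alpha = 1e-4).
- Predicted probabilities clip the logit at ±36 so floating-point
  saturation cannot return exactly 0 or 1.
- Bisection for the intercept offset runs 200 halvings on [−60, 60].
- Tests and the acceptance script use scaled problem sizes chosen to keep
  statistical assertions sharp: n = 50 000 for coefficient recovery,
  n = 2000 with B = 200 for selection accuracy, n = 20 000 for calibration
  slope, n = 1612 (the default cohort size) for the end-to-end run.

## Known limitations

- Stepwise-AIC consensus is a heuristic; the exhaustive-oracle guarantee is
  only asserted for small candidate sets.
- Bootstrap percentile intervals can be narrow for metrics near 0 or 1.
- The EPV screen's carrier-based event count is one reasonable reading of
  the "10 events per variable" rule; other definitions (total events, or
  screening continuous variables too) would change which decoys survive.
- Single imputation understates uncertainty relative to multiple
  imputation; acceptable at <5% missingness but not beyond.
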