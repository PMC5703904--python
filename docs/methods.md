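# Methods

## The problem and the study design

The package models first-trimester prediction of gestational diabetes
mellitus (GDM) as binary classification on a subjects × features table:
features are acquired at registration (≤ 13 weeks' gestation), labels
c ∈ {−1, +1} come from the second-trimester OGTT. Two properties dominate
the design: heavy, feature-specific missingness (patients take different
tests at different visits) and class imbalance (≈ 14% positives), under
which accuracy-maximising classifiers degenerate to the majority vote.

The implemented loop is: simulate (or load) a cohort → filter by
missingness → discretise continuous features → max–min normalise →
multiple imputation by predictive mean matching → stratified 90/10
train/test split → 10-fold cross-validation of five baselines and the
cost-sensitive ensemble → a sweep over the positive-class cost λ₁ →
held-out evaluation → significance analysis.

## Synthetic cohort generator

Because clinical EHR extracts of this kind are not publicly shareable, the
generator fabricates cohorts with the marginal structure of a reference
hospital cohort of 4,378 pregnancies and 49 first-trimester predictors:

* **Continuous** anthropometrics (height, BMI, maternal and paternal age,
  marriage years, parity): Gaussian draws from the published mean and s.d.,
  clipped to the published min/max.
* **Binary** flags (high-risk pregnancy, non-native residence): Bernoulli
  draws at the published rates (0.13 and 0.12).
* **Ordinal** laboratory indices on the low/normal/high scale {1, 2, 3}:
  level probabilities solved in closed form from the published mean and
  variance (`p3 − p1 = mean − 2`, `p1 + p3 = var + (mean − 2)²`), with the
  variance clipped to the nearest feasible point on the simplex when the
  printed moments are not exactly representable. Labs published on a 0–2
  coding are shifted by +1 onto the common scale.
* **Missingness**: each cell of feature j is masked independently with that
  feature's published missing fraction (missing completely at random). The
  real mechanism is visit-driven and heterogeneous; MCAR is the minimal
  model consistent with per-feature rates, and nothing downstream assumes
  more.
* **Labels**: p(+1 | x) = σ(β₀ + Σ_j β_j z_j) over column-standardised
  features, with nonzero weights on a documented five-feature subset
  (high-risk flag 1.0, delivery age 0.8, BMI 1.0, fasting plasma glucose
  0.8, thyroid-peroxidase antibody 0.6). These magnitudes were fixed once
  so that a plain logistic baseline lands in the 0.80–0.90 AUC band typical
  of first-trimester GDM prediction; the intercept β₀ is calibrated by
  bisection until the cohort-average positive probability is within 0.001
  of the target prevalence (default 0.14).

What the generator does **not** emulate: longitudinal visit structure,
informative (MNAR) missingness, feature–feature correlations beyond those
induced by the label, or the exact published medians/variances per feature.
Tests passing on these cohorts therefore certify the machinery and its
statistical behaviour under a known truth, not clinical performance on real
EHR data — in particular, the synthetic minority class is cleaner and more
separable at the decision threshold than the real one, which shows up as
higher TPR (and slightly higher FPR) than the real-data regime.

## Preprocessing conventions

* **Missingness filter**: drop features with missing fraction strictly
  above the threshold (default 0.5), then subjects, in that order. A
  stricter stage (0.2 features / 0.05 subjects) is available through
  configuration but off by default. The filter is idempotent.
* **Discretisation**: equal-frequency binning (default 3 bins, matching the
  labs' low/normal/high coding) computed on observed training values;
  features with fewer distinct values than bins fall back to distinct-value
  codes. Fitted cut points are reapplied to held-out data, never refitted.
* **Max–min normalisation**: continuous features only; (min, max) estimated
  on training data and reapplied to test data, where values may legitimately
  fall outside [0, 1]. A constant column maps to 0 with a warning rather
  than an error. In the default pipeline order (filter → discretise →
  normalise → impute) discretisation usually leaves nothing continuous to
  normalise; the step matters when discretisation is disabled.
* **Imputation**: predictive mean matching, m = 5, k = 5 donors. Each
  incomplete feature is regressed (OLS) on the complete features over
  observed rows; per imputation, coefficients are drawn from the asymptotic
  normal of the fit, missing rows get predicted means, and the observed
  value of one of the k nearest donors (by unperturbed predicted mean) is
  copied. Every imputed value is, by construction, an observed value of its
  feature. Completed tables are pooled cell-wise: median for continuous,
  mode with ties toward the lower code for ordinal/binary; a
  first-imputation mode is available. Chained equations across many
  incomplete features are deliberately out of scope — at the reference
  missingness levels (≤ 4% per feature) single-pass per-feature PMM
  suffices.
* **Partitioning**: train size = ⌊fraction·n⌋ (4,378 → 3,940/438 at 90/10),
  stratified by label with largest-remainder rounding; k-fold splits are
  stratified with fold sizes differing by at most one.

## Base learners

All five learners share one contract: score s ∈ [0, 1] (probability of
+1), label = +1 iff s ≥ threshold (0.50 by default, ties to +1), confidence
= max(s, 1 − s). All accept per-instance weights; for integer weights every
weighted fit coincides with the fit on the row-duplicated data (exactly for
the likelihood-based learners, to optimiser tolerance for the rest).

* **Logistic regression** with forward selection: main effects plus
  intercept; each step adds the candidate minimising the weighted deviance
  if its likelihood-ratio p-value is below 0.05, else stops.
  Quasi-separation falls back to a ridge-stabilised fit with a warning.
* **Naive Bayes** (the "Bayesian network" slot): weighted maximum-likelihood
  categorical model with Laplace smoothing 1, for post-discretisation
  features; unseen levels at prediction receive the smoothing mass. A full
  Markov-blanket structure search is not attempted — the reference setup
  treats this learner as naive Bayes in practice.
* **Boosted multilayer perceptron**: 10 components, one hidden layer of
  round((p + 2)/2) units, each trained ≤ 250 cycles with early stopping on
  an internal 30% holdout; weights enter by weighted resampling (the
  optimiser has no native instance weights) and components combine by
  discrete-boosting weights applied to component probabilities.
* **RBF-kernel SVM**: soft margin (C = 1, stop tolerance 1e-3) honouring
  instance weights; decision values are calibrated to probabilities by a
  Platt-style logistic fit on out-of-fold decision values (3 stratified
  folds) when the data allow, else in-sample. The epsilon setting listed
  for the reference configuration is a regression parameter irrelevant to
  classification; it is stored for fidelity and ignored with a notice.
* **CHAID tree**, implemented from scratch: at each node and feature, the
  pair of categories whose 2×2 chi-square with the label is least
  significant (p > 0.05) is merged, up to 200 iterations; the merged
  table's p-value is Bonferroni-adjusted by the number of possible nominal
  merges, and the node splits on the smallest adjusted p below 0.05.
  Growth stops at depth 16, parents under 2% of n, or children under 1% of
  n; leaf score = weighted positive fraction; unseen categories at
  prediction route to the heaviest child.

## The cost-sensitive ensemble

Costs λ₁ (positives) and λ₂ (negatives, fixed at 1 by default) are applied
as instance weights normalised to mean 1. The constrained-optimisation view
of cost-sensitive learning (maximise accuracy subject to a hard cost bound)
is represented in `CostSpec.c_hard` but never solved as a program — the
rescaling realisation is the method; the bound is metadata.

`train_cshm` holds out a stratified 20% of the training fold, trains the
bases (LR, SVM, CHAID by default) on the remaining 80% with rescaled
weights, discards any base with holdout AUC < 0.6 (if all fail, the single
best is kept with a warning), and refits the survivors on the full training
fold. Two combination rules ship: **confidence-weighted voting** (default;
summed confidences per class, ties to the class holding the single largest
confidence, then to −1) and **sign-average** (majority of base labels,
exact ties to −1 — the conservative choice in an imbalanced setting where
positives should require strict evidence). A `max_confidence` rule
(highest-confidence base wins outright) is provided because the reference
configuration's "(maximum)" qualifier is ambiguous between the two
readings. The ensemble's ROC score is the confidence-weighted mean of base
probability scores — the voting share alone is too coarse a statistic for
ROC analysis — while the reported ensemble confidence is the winning vote
share, which with three bases can legitimately fall below 0.5.

## Evaluation and significance

ROC curves are standard empirical step curves over all distinct score
thresholds (ties grouped); AUC is the trapezoidal area, which equals the
tie-corrected Mann–Whitney concordance (verified against an O(n²) oracle).
Confidence reports give mean confidence over correct and incorrect
predictions, the confidence range, and a coverage table at levels
0.50–0.95.

DTPR(Y₁ − Y₂) is TPR(Y₁) − TPR(Y₂) read off the two ROC curves by step
interpolation at a shared FPR grid (default: union of both curves'
breakpoints; the reference analysis's threshold-count construction is not
published, so the grid is configurable). The DTPR sequence is tested
against 0 with a one-sample t-test (df = n−1, 95% CI); applying a location
test across thresholds ignores their dependence — this is kept deliberately
because it is the conventional reporting device, with DeLong's test as the
statistically grounded companion. `t_from_summary` recomputes the identical
test from (n, mean, sd) alone, which is how published comparison rows are
verified. DeLong's two-sided test for correlated AUCs uses the fast
placement-value construction; it is cross-checked in the test suite against
frozen reference values from R's pROC on a seeded fixture, and its null
calibration (type-I error within [0.03, 0.07] at α = 0.05) is verified by
simulation.

## Numerical and reproducibility choices

* All randomness flows from explicit integer seeds; the pipeline fans one
  global seed out to per-stage seeds via SHA-256 so stages are independently
  reproducible. Identical configs give byte-identical reports.
* Intercept bisection tolerance 0.001 on prevalence; logistic fits use
  lbfgs with unpenalised likelihood (separation → ridge fallback).
* Degenerate cases are defined, not errors where avoidable: constant
  normalisation columns → 0 with a warning; zero-variance t-tests and
  single-class ROC inputs raise; DeLong on identical scores returns p = 1
  exactly; undefined TPR/FPR (empty class) is NaN and flagged.
* p-values below 1e-300 serialise as the string "<1e-300".

## Problem sizes used in the shipped checks

The test suite exercises the full reference geometry where it is cheap
(split arithmetic and the cost-sensitivity sweep at n = 4,378; coefficient
recovery at n = 50,000) and toy geometries elsewhere. The end-to-end
pipeline tests run at n ≈ 400–700 with m = 2 imputations and
cross-validation disabled — the orchestration logic, not the statistics, is
under test there. `scripts/acceptance.py` runs one full n = 4,378 cohort
end to end.

## Known limitations

* MCAR missingness and independent features make imputation easier than on
  real EHR data; PMM quality on synthetic cohorts overstates real-world
  performance.
* The boosted-MLP component weighting assumes standard discrete boosting;
  the reference implementation's preset is proprietary and may differ.
* CHAID uses the nominal Bonferroni multiplier for all discrete features,
  including ordinal ones (where a restricted adjacent-merge adjustment
  would be slightly more powerful).
* Under strong cost asymmetry (λ₁ = 100 at prevalence 0.14) the effective
  positive mass is ≈ 94%, so the ensemble predicts nearly everyone
  positive: sensitivity saturates at the cost of specificity. The sweep is
  a trade-off dial, not a free lunch.
* At the default generator calibration the symmetric-cost ensemble's test
  FPR averages ≈ 0.025 over seeds rather than the near-zero regime seen on
  real data — a direct consequence of the synthetic minority tail being
  separable at the 0.50 threshold (see the generator section).
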