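# Methods

## Data model and conventions

A cohort is a numeric feature table (samples × features) plus per-sample
metadata: an environment label (the contributing center) and a binary
outcome. Feature names follow the radiomics convention
`<filter>_<class>_<name>_<sequence>_<region>`; only the filter token may
contain dots, the sequence vocabulary is {T1, cT1, T2, FLAIR} and the
region suffix {L1, L2, L3} encodes enhancing tumor, nonenhancing
tumor/necrosis, and edema.

**Positive class.** Wild-type is the positive class by default
(configurable). This is the only convention under which the published
confusion matrices of the study this package models reproduce the
published sensitivities and specificities (e.g. the stratified-split
stability+invariance model: sens = 6/7 ≈ 0.86 and spec = 13/15 ≈ 0.87
only if wild-type counts as positive).

**Confusion matrices** are oriented rows = prediction, columns =
reference. **Missing values are rejected, not imputed** — silent
imputation would contaminate the invariance analysis with a second,
untested model. **CI endpoints are truncated (not rounded) to 2 decimals
in display fields**; truncation is the only convention that reproduces
published endpoints such as 9/11 → upper 0.94 (computed 0.9487) and 2/3 →
[0.20; 0.93]; full-precision values are always retained alongside.

## The invariance test

For a subset S and environment e, a logistic model of the outcome on X_S
is fitted on the complement of e (ridge-stabilized with a tiny L2 term,
C = 10⁴, so perfect separation in small complements stays finite).
Pearson residuals r = (y − p̂)/√(p̂(1−p̂)) and the score components
r·x_j, j ∈ S, are computed on e and on the complement; each of the
|S|+1 mean differences is tested with a Welch two-sample t-test, the
p-values are Bonferroni-combined within the environment and the
per-environment p-values Bonferroni-combined across environments. The
empty subset uses the intercept-only (prevalence) model and only the
residual-mean test.

Why these statistics and not others:

* Under a correct invariant model, E[r | x] = 0 and E[r·x_j | x] = 0 at
  every covariate value. Their means are therefore centered in every
  environment *regardless of how the feature distributions shift across
  centers* — and cross-center covariate shift is precisely the situation
  the method must operate in, since per-center prevalence differences are
  induced by shifts in the causal features.
* Deviance residuals do not have this property: their conditional mean
  is a nonzero function of p̂(x), so a center whose feature distribution
  differs moves the residual mean even under a perfectly invariant
  model. Empirically this rejects the true causal set with probability
  approaching 1 as per-center n grows.
* Any dispersion comparison (normal-theory F, or robust Brown–Forsythe)
  is confounded the same way for a binary outcome: the residuals'
  conditional distribution shape depends on p̂(x) even though the
  conditional variance is exactly 1, so variance-type components were
  deliberately dropped.
* The residual mean alone is blind to pure slope misfit (a model wrong
  in slope but right on average); the score components close that blind
  spot — they are exactly the moments the in-sample likelihood equations
  set to zero, so a systematic nonzero score mean on the held-out
  environment signals a non-transferring model.

Measured operating characteristics (each from a dedicated simulation in
the test suite): null rejection rate ≈ 0.02–0.04 at α = 0.05 when one
mechanism is split arbitrarily into environments; acceptance of the true
causal set ≈ 0.83–0.90 under the default generator's shifts; rejection
of environment-dependent (spurious) subsets ≈ 1.0 at n = 500/environment.

**Selection.** All subsets of the preselection pool up to
`max_subset_size` (default 4; enumeration capped at 50,000 subsets) are
tested, including the empty set; the selection is the intersection of
subsets with p > α (α = 0.05 by default, matching the reference study's
significance level). Subsets whose complement fit is infeasible
(single-class complement) are rejected with p = 0 and logged rather than
skipped. An empty intersection — nothing accepted, or accepted sets that
intersect to nothing (acceptance of the empty set forces this) — flags
`fallback_used`; downstream recipes then train on the preselection pool
with a prominent warning, since a runnable model is still required.

## Preselection

* **Lasso**: L1-logistic path on standardized features over a 50-point
  grid log-spaced 3 decades below λ_max = ‖Xᵀ(y − ȳ)‖∞/n; penalty chosen
  by repeated stratified CV maximizing MCC; support ranked by
  |coefficient|, truncated to `max_features` (default 20 — the
  invariance stage enumerates subsets, so the pool must stay small).
* **Stability**: 100 class-stratified subsamples of fraction 0.5; a
  feature counts as selected in a subsample if it is nonzero anywhere on
  the penalty grid; frequency threshold 0.6. These are conventional
  stability-selection settings; all are configurable. Subsampling is
  class-stratified with at least one sample per class so that a center
  contributing a single minority case never produces a one-class
  subsample.

## Classifier and tuning

The final model is L1-logistic on features standardized with
training-split statistics (standardization makes one penalty comparable
across features; the stored model carries the constants). λ is chosen
from a 50-point grid (3 decades below λ_max) by 10×3 repeated stratified
CV maximizing MCC at probability threshold 0.5; ties break toward the
larger penalty (sparser model); the model is refit on all training data
at λ*. MCC of a degenerate confusion matrix (any zero marginal) is
defined as 0 — the standard convention, which keeps tiny CV folds from
dividing by zero. The probability threshold is fixed at 0.5; no
threshold tuning is performed.

## Evaluation

* **Scenarios.** Leave-one-center-out: each center in turn is the test
  set; preselection, invariance (with the remaining centers as
  environments) and tuning see only the training centers. Stratified
  split: a single outcome-stratified 70/30 partition (scikit-learn's
  per-class rounding; n = 77 gives 53 train / 24 test).
* **Intervals.** AUC uses the rank/midrank estimator with a
  class-stratified percentile bootstrap CI (2000 replications). MCC uses
  the same stratified bootstrap (the reference study prints MCC CIs
  without stating a construction; a proportion-type interval does not
  apply to MCC). Accuracy, sensitivity and specificity use Wilson score
  intervals. A test set missing one class gets its class-dependent
  metrics flagged undefined rather than fabricated.
* **Comparisons.** Paired class-stratified bootstrap of ΔAUC;
  p = 2·min(frac(Δ ≤ 0), frac(Δ ≥ 0)), floored at 1/n_boot; Holm
  step-down adjustment across the pairwise comparisons of a scenario.
* **NIR.** The no-information rate is the test-set majority-class
  fraction; the test is the exact binomial tail P(X ≥ correct | n, NIR).
* **CV intervals** summarize the per-fold metric values at λ* as mean and
  percentile interval — a convention-dependent construction, flagged as
  such in reports.

## Synthetic multicenter generator

The generator provides ground truth for every downstream stage. Causal
features are Gaussian with environment-specific means; the outcome is
logistic on them with coefficients shared by all environments — so
P(y | causal) is invariant while marginal prevalence varies by center.
Spurious features are outcome *consequences* with environment-varying
strength (γ_e·y + noise): predictive within a center, non-transferable
across centers. Noise features are outcome-independent with
per-environment location/scale batch effects. Per-center prevalences are
realized by solving the causal mean shift from the target prevalence with
the standard logistic–probit moment matching; prevalence shifts are
never injected through per-environment intercepts, which would break the
invariance the method assumes.

Defaults mirror the reference cohort's structure: four centers of
7/12/36/22 cases with wild-type prevalences 3/7, 1/12, 7/36, 15/22;
dimensionality is kept modest (3 causal, 5 spurious, 200 noise features)
— the high-dimensional regime's *structure*, not its 12k-feature scale.
All distributional choices are stand-ins: real radiomics features are
heavy-tailed, blockwise correlated (thousands of features from a few
dozen images), and their site effects are not purely location/scale.
Passing tests therefore demonstrate the pipeline's statistical behavior
under its stated assumptions, not performance on real imaging data.

## Problem sizes used in the test suite

Simulation-backed properties run at deliberately chosen desk scales:
null calibration over 500 two-environment datasets of n = 120; coverage
over 100 draws of the default 4-center generator at 200 cases/center
(subset enumeration capped at size 3); bootstrap-CI coverage over 500
binormal datasets of 60 + 60 scores with 500 replications; the
generalization-gap contrast over 50 seeds of a 4-center design
(150/150/150/80) whose spurious-edge sign flips in the held-out center,
with reduced CV settings (12-point grid, 2 repeats). These sizes keep
each property suite to minutes while leaving clear Monte-Carlo margins.

## Known limitations

* The invariance test needs ≥ 2 environments and is Bonferroni-
  conservative; with many centers its power per comparison drops.
* Covariate shift interacts with estimation error of the complement fit;
  at very small per-center n the true set can be rejected slightly more
  often than α (measured ≈ 0.10–0.17 under strong shifts).
* Exact recovery of the full causal set is not guaranteed — identifying
  a causal feature requires the environments to shift it (or its
  prevalence contribution); unshifted causal features may drop out of
  the intersection, which is why partial recovery with zero false
  inclusions is the typical outcome.
* With per-center samples in the single digits (as in the smallest
  centers of the reference cohort), the Welch tests carry little
  evidence and acceptance becomes near-automatic; the procedure then
  leans entirely on the preselection pool.
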