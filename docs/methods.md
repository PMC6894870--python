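# Methods

## The model

The package implements a reconstruction-error (RE) routed pair of deep
neural-network classifiers for binary disease-risk prediction on
tabular risk factors, together with everything needed to exercise it:
a synthetic cohort generator, an evaluation harness and feature-ranking
procedures.

An autoencoder fitted to a data distribution reconstructs typical
samples well and atypical samples poorly, so the per-sample RE

    RE_i = (1/d) * sum_j (x_ij - x̂_ij)^2

is an anomaly score with respect to whatever data the autoencoder was
trained on. The method uses this twice:

1. **Routing.** A *general* deep autoencoder is fitted on all training
   rows (after z-scoring). The routing threshold is

       threshold = mean(RE) + dispersion(RE)

   over the training REs, where the dispersion is the population
   standard deviation by default. The training set is split into a
   high-RE group (RE strictly above the threshold) and a low-RE group
   (ties go low, matching the strict "exceeds" rule), and one
   classifier network is trained on each group. At prediction time a
   sample is scored by the network of the group its own general-RE
   falls into. The rationale: a high-variance subset biases a single
   classifier; isolating it lets each network fit a more homogeneous
   conditional distribution.
2. **Feature engineering.** A *risky* autoencoder is fitted on the
   high-risk training rows only. Its RE is appended to the risk
   factors as a 15th input: low-risk samples, which this model never
   saw, tend to reconstruct worse, so the scalar carries class signal.

Architectures are fixed by specification: the autoencoder has six
affine layers (14 → 10 → 7 → 4 → 7 → 10 → 14 by default; only depth
and activations are structural, widths are configurable) with
rectifier activations through the encoder and hyperbolic tangent
through the decoder *including the output layer*; each classifier is
15 → 10 → 7 → 5 → 3 → 1 with rectifier hidden layers and a sigmoid
output. Both are trained with minibatch Adamax (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8) at learning rate 0.001, batch size 32, minimizing mean
squared error — also for the classifier, where MSE-on-sigmoid is
unusual but deliberate; cross-entropy is a configuration option.
Training the networks in plain numpy keeps seeded fits reproducible
bit-for-bit; the networks are small enough that this costs nothing.

A tanh output on standardized inputs cannot reproduce values outside
[-1, 1]; the residuals this leaves on extreme z-scores are part of the
method (they are precisely what makes extreme samples high-RE). A
linear-output escape hatch exists but is off by default.

A PCA variant replaces both autoencoders with projection onto the top
principal components and back (default 4 components, mirroring the
autoencoder bottleneck); everything else is identical. It serves as a
comparator, and in tests as an independently checkable backend (its RE
is verified against an eigendecomposition oracle).

## Conventions and numerical choices

- **Positive class** is high risk throughout; precision, recall,
  specificity and F-measure use the standard definitions; undefined
  ratios (zero denominator) are reported as flagged nulls, never as 0.
- **Population (1/n) convention** everywhere a variance or SD is
  computed (standardizer, threshold dispersion), fixed so that exact
  tests are well-defined.
- **Threshold dispersion**: default is the population SD; a literal
  mean-plus-variance variant is selectable
  (`convention="variance"`). With REs of magnitude « 1 the variance
  variant yields a lower threshold and a larger high-RE group.
- **RE reduction**: the per-sample RE is the scalar mean of squared
  coordinate differences (not a per-coordinate vector) — the 15-wide
  classifier input forces a scalar, and the mean matches the training
  objective, so mean(RE vector) equals the optimizer's recorded
  training loss exactly.
- **The RE feature is standardized jointly** with the other 14 columns
  before entering the classifiers: raw REs are orders of magnitude
  smaller than z-scores and would otherwise be washed out. Prediction
  applies the stored 14-column standardizer, computes both REs, then
  the stored 15-column standardizer.
- **Categorical features stay ordinal**: each keeps its survey integer
  code (including the special codes 8/9/88) as a single numeric
  column, because the 15-neuron input layer leaves no room for one-hot
  blocks. Constant columns and unknown codes are rejected with named
  errors; missing values are rejected, not imputed.
- **Leakage control**: every fitted component — both standardizers,
  both backends, the threshold and both networks — is fit inside the
  training portion only and refit per CV fold.
- **Seeding**: one master seed per fit; the general backend, risky
  backend and the two networks consume sub-seeds derived through a
  seed sequence, so a fitted bundle serializes byte-identically across
  runs with the same seed.
- **Folds**: stratified k-fold via a seeded within-class round-robin
  deal that keeps overall fold sizes within one row of each other and
  each class split as evenly as possible.
- **AUC** is computed from predicted scores (never hard labels) and
  equals the Mann–Whitney pair-win fraction with ties worth one half.
  The Hanley–McNeil closed form supplies its standard error, the z
  test against AUC = 0.5 (two-sided p) and the 95% CI; an AUC of
  exactly 0 or 1 is reported with zero SE, infinite z and p = 0.
- **Mean ROC curves** are vertical averages of per-fold curves over a
  fixed 101-point false-positive-rate grid (no recipe is canonical;
  this one is the common choice), pinned to (0,0) and (1,1).
- **Comparators** (naive Bayes, k-NN, decision tree, random forest,
  SVM) delegate to scikit-learn; defaults are the configurations the
  comparison tables report (k = 19, 110 trees, gini, RBF kernel), and
  a parameter grid can be configured to run an inner 3-fold search
  (e.g. k ∈ 2..20, trees ∈ 10..150).
- **Feature ranking** scores each leave-one-out model by
  cross-validated accuracy with a fixed seed (less noisy than the
  single split the original procedure used; `single_split=True`
  restores that mode). Ties in the accuracy drop break by canonical
  feature order. Recursive elimination removes the least-important
  features cumulatively, one more per step, down to one survivor.

## The synthetic cohort generator

Real cohorts of this kind come from a national health survey and are
not redistributable, so the generator emulates the published per-class
feature distributions: 7 continuous risk factors are drawn per class
from the printed means/SDs, 7 categorical risk factors from the
printed per-class count tables normalised to probabilities (tiny "no
response" levels are kept). Class sizes default to the survey's
13,075 low-risk / 12,915 high-risk records.

Choices the printed tables do not determine:

- **Independent marginals.** Only marginal mean/SD and counts are
  printed, so features are drawn independently within class. Real
  risk factors are correlated (age with blood pressure, BMI with waist
  circumference); synthetic performance numbers therefore do not
  transfer to real data, and tests against this generator demonstrate
  mechanism, not clinical accuracy.
- **Moment-matched nonnegative sampling.** Continuous features are
  truncated to [mean − 4·SD, mean + 4·SD] ∩ [0, ∞), with the
  underlying location/scale solved numerically so the *truncated*
  distribution reproduces the target mean and SD exactly (naive
  truncation would bias low-risk age by ≈ 0.46 yr and high-risk
  neutral fat by ≈ 23 mg/dL). Where no truncated normal on
  nonnegative support can attain the target SD/mean ratio — which
  happens for variance-inflated neutral fat — a moment-matched
  lognormal is used instead, the natural family for such right-skewed
  nonnegative quantities.
- **Disorder flags.** The six flags (hypertension, dyslipidemia,
  stroke, myocardial infarction, angina, hyperlipidemia) are drawn
  from a logistic link on the standardized continuous features with
  class-dependent intercepts, then overridden for class consistency
  (low-risk rows carry no flags; a high-risk row with no sampled flag
  gets its most probable one). The link makes flags plausibly
  co-occur; it is not an epidemiological model. The label is always
  the OR of the flags.
- **Planted high-variance subgroup.** A fraction (default 0.15) of
  rows in *both* classes has its continuous features redrawn with the
  SD multiplied by `anomaly_inflation` (default 2, mean-preserving),
  recorded in a bookkeeping column models never see. This gives the
  RE threshold genuine structure to isolate; with the fraction at 0
  the routed and single-classifier variants coincide to within noise.

## Problem sizes used in the shipped checks

The full training schedule (5000 epochs) and survey-scale cohort are
available through configuration, but the shipped tests and the
reproduction script run a desk-scale profile chosen as the smallest
configuration where every mechanism is visibly exercised: cohorts of
a few hundred to 5,000 rows, 200 training epochs (40–60 for pure
plumbing tests), 10-fold cross-validation for the headline run and
3-fold, 5-seed runs for the ablation ladder. At this scale the routed
method's cross-validated AUC on the default synthetic cohort is
typically ≈ 0.9, and the ablation ladder (single network → routed
pair → routed pair + RE feature) is checked for the direction of the
effect (no degradation), not its published magnitude, which belongs to
the original survey data.

## Known limitations

- No feature correlation in the generator beyond the class structure;
  no survey weights, missing-data patterns or measurement error.
- No calibration of predicted probabilities; the 0.5 decision cutoff
  is configurable but not tuned.
- The comparator harness reproduces table *structure*; published
  values from the original survey extract are not reproducible without
  that data and are not targets of the test suite.
- Adamax/minibatch training is deterministic per seed and platform but
  not guaranteed bit-identical across BLAS implementations.
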