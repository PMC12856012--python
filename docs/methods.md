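# Methods

This note documents the models, procedures and numerical choices behind
the package, and what the synthetic-data experiments do and do not
demonstrate.

## Problem and data model

The task is binary sex classification of narrow-clawed crayfish
(*Pontastacus leptodactylus*) from two kinds of data: a morphometric
table (one row per animal; weight, carapace length/width, abdomen
length/width, cheliped length/width/height, plus generic extra features
up to 11 columns) and grayscale photographs downscaled to 28×28 pixels.
The reference study measured 112 animals (62 female, 50 male; class
ratio 0.806:1) and photographed 1,277 specimens (717 female, 560 male;
ratio 0.781:1), splitting the images 895 train / 382 test.

The real data live in an external repository; the package ships a
synthetic generator so every pipeline stage is testable offline.

### Synthetic tabular data

Each feature is Gaussian within sex with a configurable standardized
mean separation `effect_size` (Cohen's d, unitless): for feature *j*,
`x = mu_j + sigma_j * (z + d * 1[male])` with per-feature location/scale
set to plausible morphometric magnitudes (grams/millimetres; affine, so
d is unaffected). Missingness is MCAR at `missing_rate` — the simplest
mechanism consistent with per-column mean/median/mode imputation.
Outliers displace a fraction `outlier_rate` of non-missing cells by
`outlier_scale` within-class SDs with random sign.

What this does not emulate: inter-feature correlation structure (real
morphometrics are strongly collinear), allometric scaling, lake/season
covariates, and measurement error models. Passing tests therefore
certify the pipeline's mechanics and statistical behaviour, not field
performance on real animals.

### Synthetic images

Each class is a single parametric template — an ellipse body plus two
frontal claw protrusions on a dark background — with sex-dependent
geometry (males more elongated, larger claws) and binary intensities
{0.1, 0.9}; i.i.d. Gaussian pixel noise `noise_sd` (grayscale units,
default 0.05) is added and clipped to [0, 1]. With zero noise each class
is exactly one template. Pose, illumination and scale variation of real
photographs are deliberately not modelled; a linear probe already
separates the classes, so image experiments exercise plumbing
(partitioning, feature extraction, leakage control), not hard vision.

The default test partition mirrors the study's printed counts (216 F /
166 M of 1,277) when the class counts match the study's, else
round(0.3·n) per class.

## Preprocessing

* **Imputation** — mean / median / mode / kNN per feature. Mode ties
  break to the smallest modal value. kNN (k=5 default) uses plain
  Euclidean distance over features observed in both rows, uniform
  weighting over the k nearest donors that observe the target feature.
  Observed cells are never altered.
* **IQR capping** — per feature, values outside
  [Q1 − m·IQR, Q3 + m·IQR] are set to the nearest boundary, m = 3.
  Quartiles use linear interpolation between order statistics (the
  common scientific-software default). The operation is idempotent.
* **Scaling** — standardization z = (x − u)/s with training-set mean and
  population SD (divide by n), or min–max to [0, 1]; fitted inside each
  training split only and applied to the held-out data without clipping.
  A constant feature under standardization gets scale 1 with a warning
  rather than an error, keeping degenerate synthetic inputs runnable.
* **Fold plan** — ten folds with exact per-fold class counts. For
  62 F / 50 M the study's printed fold table is reproduced
  (F: 7,7,6,6,6,6,6,4,7,7; M: 5,5,5,5,5,5,5,7,4,4); otherwise shuffled
  rows are dealt round-robin per class, so per-class fold sizes differ
  by at most one.
* **Images** — luminance grayscale (ITU-R 709 weights), bilinear resize
  to 28×28, scaling to [0, 1], then (x − 0.5)/0.5 into [−1, 1].

Pipeline order on tabular data is folds → impute → IQR → per-fold
scaling. Imputation and capping are computed on the full table (as in
the reference protocol); only scaling is fold-local.

## Autoencoder feature extraction

Stage one: 1×28×28 → conv(64, k3, s2, p1) → ReLU → conv(128, k5) → ReLU,
giving a 128×10×10 code (12,800 features flattened); the decoder mirrors
with transposed convolutions and a sigmoid head. Stage two consumes the
128×10×10 codes: conv(256, k3, p1) → ReLU → conv(512, k5) → ReLU, a
512×6×6 code (18,432 features), with a transposed-conv decoder back to
128×10×10. These defaults satisfy the architectural constraints the
benchmark fixes (two conv layers per stage, a 128-channel code feeding
stage two, flattened dims 12,800 / 18,432); every layer spec is
overridable, and construction fails loudly if a spec misses its target
dimension.

Training minimizes mean squared reconstruction error with Adam
(lr 10⁻³, batch 16, shuffle on), at most 100 epochs, stopping early when
the epoch loss fails to improve by more than 10⁻³ for 5 consecutive
epochs. Early stopping monitors the training loss; no validation split
is used for the autoencoders. Two numerical choices deserve note:

* the stage-one sigmoid head is compared against the images remapped
  from [−1, 1] back to [0, 1] (the encoder still sees [−1, 1] input);
* stage-one ReLU codes are unbounded above, so stage two trains on codes
  divided by their maximum over the training codes, keeping the sigmoid
  reconstruction well-posed. Feature extraction uses the same rescaled
  codes.

Both stages train on the training partition only; an audit object
records exactly which row indices each stage consumed, and tests assert
disjointness from the test partition.

The networks are implemented directly in numpy (im2col convolutions,
manual backprop, float64); at 28×28 benchmark scale this trains in
seconds and keeps every numerical step inspectable.

## Kolmogorov–Arnold network

Each edge (i → j) of a KAN layer carries a learnable univariate
function: output_j = Σᵢ Wb[j,i]·silu(xᵢ) + Σᵢ Σₖ Ws[j,i,k]·Bₖ(xᵢ), where
Bₖ are B-spline basis functions of order S over a uniform grid of G
intervals (G + S coefficients per edge) and silu(x) = x·sigmoid(x) is
the smooth base path. The basis is evaluated by the Cox–de Boor
recursion over an extended knot vector (G + 2S + 1 knots), so
standardized inputs slightly outside the nominal domain [−1, 1] still
fall on defined knots; far outside, the spline term vanishes and the
base path carries the signal. Inside the domain the basis is a partition
of unity (checked to 10⁻⁹), and the forward pass is verified against a
scalar double-loop oracle (10⁻¹⁰) and full finite-difference gradient
checks (10⁻⁴ relative).

Defaults: G = 5, S = 3, domain [−1, 1], layer widths
[input, 256, 128, 64, 32, 1], sigmoid output, binary cross-entropy on
logits (numerically stable log-sum-exp form). Weights initialize
uniformly at ±1/√in_dim, spline coefficients ten times smaller, chosen
for stable early loss. Training is full-batch (deterministic given the
seed) with Adam (default) or SGD, ReduceLROnPlateau-style decay (factor
0.5 after 5 stagnant epochs) and early stopping (patience 10,
delta 10⁻⁴). Male is predicted iff the output probability is ≥ 0.5.

The grid is fixed (non-adaptive); the tuned hyperparameter values of the
original experiments are not recoverable, so only the architecture and
training regime are fixed here, with G, S and the learning rate exposed
to the tuning harness.

## Classifier harness and evaluation protocols

Five canonical families come from scikit-learn (MLPClassifier,
KNeighborsClassifier, GaussianNB, RandomForestClassifier, SVC with RBF
kernel); the KAN is wrapped in the same estimator interface. Naive Bayes
is never tuned. Default grids (overridable): MLP hidden sizes
{(50,), (100,), (100, 50)} × alpha {10⁻⁴, 10⁻³}; KNN k {3, 5, 7, 9} ×
{euclidean, manhattan}; RF trees {100, 300} × depth {none, 10}; SVM C
{0.1, 1, 10} × gamma {scale, 0.1}.

* **Tabular protocol** — grid search by rotating ten-fold accuracy on
  the fold plan (scaler refit inside each training split; ties break to
  the first candidate in grid order), then pooled ten-fold evaluation
  with the chosen hyperparameters: each fold predicted once by a model
  trained on the other nine, all 112 predictions pooled into a single
  confusion matrix. Reusing the same folds for tuning and evaluation
  replicates the reference procedure and is optimistic; the harness
  exposes everything needed to run a clean nested variant (separate
  fold plans per stage) but reports the faithful protocol by default.
* **Image protocol** — hyperparameters tuned by ten-fold CV within the
  training features only, one final fit on all training features, one
  evaluation on the untouched test partition. Row-id overlap raises a
  leakage error.

Metrics: accuracy, sensitivity (recall), specificity, precision, F1 and
MCC, with male as positive class. Zero-denominator ratios report 0 with
a degeneracy flag rather than raising, so degenerate folds cannot abort
a sweep. Display rounding is half-away-from-zero at 3 decimals; internal
values keep full precision. Published rows can be inverted back to
integer confusion matrices via recall/specificity; the consistency check
also accepts two-step rounding (e.g. 50/62 = 0.80645 printed as 0.807),
which the source tables occasionally use.

## Paired model comparison

Both tests operate on per-sample correctness, the only reading under
which a per-sample difference is defined for categorical predictions.

* **Wilcoxon signed-rank** — differences dᵢ ∈ {−1, 0, +1}; zeros
  dropped, midranks for ties, W = min(W⁺, W⁻). Since all nonzero |dᵢ|
  equal 1 the ranks are fully tied; with ≤ 25 nonzero differences the
  exact two-sided null distribution is built by dynamic programming over
  doubled ranks, otherwise the tie-corrected normal approximation is
  used (matching reference implementations to 10⁻⁶).
* **McNemar** — χ² = (|n₁₀ − n₀₁| − 1)²/(n₁₀ + n₀₁) against χ²(1). The
  continuity-corrected form is applied verbatim, including when
  |n₁₀ − n₀₁| < 1; with no discordant pairs p = 1 by convention.

Two-sided alternatives throughout; significance at p < 0.05, annotated
with the accuracy-better model. No multiple-testing correction is
applied across the pairwise matrix, matching the reference analysis.
Under simulated equal-accuracy independent models (n = 400 samples,
accuracy 0.75, 1,000 replicates) both tests reject at 3–7%, bracketing
the nominal 5% level.

## Orchestration and reproducibility

A single `ExperimentConfig` drives each framework; one master seed fans
out to per-stage seeds as (seed·9973 + stage index) mod 2³¹. Reports,
significance matrices and a manifest (package version, config hash,
seed, accuracy-column sum) are written as CSV/JSON; a fixed config and
seed reproduce byte-identical CSVs.

Problem sizes in the shipped tests and acceptance script are chosen at
desk scale: autoencoder smoke training uses tens of images and two
epochs (the architectural dimensions 12,800 / 18,432 are
size-independent), tabular benchmarks use the study's 112-row geometry,
and the type-I calibration uses 1,000 simulated pairs. The published
accuracy tables themselves were obtained on the real photographs and are
not reproduced here; the synthetic benchmarks instead verify the
machinery (protocols, formulas, leakage control) and parameter recovery
at a known effect size (pooled ten-fold accuracy ≥ 0.9 for KAN and SVM
at Cohen's d = 3).

## Known limitations

* Synthetic features are independent within class; real morphometrics
  are collinear, which particularly affects Naive Bayes.
* Image templates are trivially separable; image-side accuracies say
  nothing about real-photo difficulty.
* The exact convolution hyperparameters and tuning grids of the original
  experiments are not recoverable from the available description; the
  defaults here satisfy the printed constraints only.
* Full-batch KAN training is deterministic but can be slow for very
  high-dimensional feature inputs (12,800+); the wrapper exposes smaller
  hidden stacks for such runs.
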