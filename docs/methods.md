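# Methods

## Overview

`expr2img` implements a multimodal classification pipeline for case/control
transcriptomics (developed around the three-class Alzheimer's setting of
AD / MCI / NC cohorts).  The idea: besides feeding a subject's expression
vector to a feed-forward network (FNN), re-represent the same vector as a
small 2D image in which genes are *placed by discriminative similarity*,
feed that image to a convolutional network (CNN), and fuse the two models'
feature vectors for the final binary decision.

The stages are:

1. **Harmonization** (`ingest`): each dataset is z-scored per gene with the
   population standard deviation, datasets are concatenated over the
   lexicographically ordered intersection of their probes, and each gene is
   min–max scaled to [0, 1] over the combined cohort.
2. **Gene selection** (`select`): LASSO of the binary task label on all
   genes.  Penalty convention: `(1/n)·||y − Xb − b0||² + λ·Σ|b_j|`,
   intercept fitted, predictors not re-standardized (they are already in
   [0, 1]).  Default λ = 1e-6.  Implemented through scikit-learn's
   coordinate descent with `alpha = λ/2`, convergence tolerance 1e-4,
   iteration cap 20 000; coefficients with magnitude above 1e-12 count as
   selected.
3. **Image construction** (`genemap`): Fisher score
   `(μ₁−μ₀)²/(σ₁²+σ₀²+ε)` per gene (population variances, ε = 1e-12);
   equal-count categorization of genes into K = 15 rank bins (ties broken
   by gene index; when sizes must differ, the larger bins take the lower
   category numbers); linear discriminant analysis with genes as
   observations (features = expression across training samples, classes =
   Fisher categories; pseudo-inverse of the within-scatter, deterministic
   sign convention on the eigenvectors); rotation of the minimal-area
   enclosing rectangle (rotating calipers over the convex hull, area ties
   broken by smallest |angle|, the applied angle normalized into
   (−45°, 45°]); min–max scaling of each axis onto the pixel grid with
   half-up rounding.  Genes colliding on a pixel are averaged at render
   time; empty pixels are 0.
4. **Models** (`nets`): FNN with dense layers 128-64-32-32 (ReLU); CNN with
   six 3×3 same-padded convolutions in pairs of 32/32, 64/64, 128/128
   filters, each pair followed by 2×2 max pooling, then dense 128 → 32.
   Both branches export a t = 32 feature vector; L1 = 1e-5 / L2 = 1e-4
   kernel regularization and dropout 0.4 sit on the last two dense layers
   of each branch.  The fusion network concatenates the two feature
   vectors (ℝ^{2t}) and applies dense 32 → dropout 0.4 → dense 32 → sigmoid.
   Training: Adam at 1e-4, batch size 30, binary cross-entropy, early
   stopping that ignores the first 250 epochs and then halts after 10
   consecutive epochs without a new best *training* loss, restoring the
   best-loss weights.
5. **Evaluation** (`evaluate`): stratified five-fold cross-validation of the
   three models on one pairwise task.  All supervised artifacts (selection,
   Fisher scores, categories, LDA map) are fitted per fold on training data
   only; the gene map records the sample IDs it was fitted on and the
   evaluator refuses to proceed if that set intersects the held-out fold.
   AUC is computed from the tie-corrected Mann–Whitney rank statistic;
   accuracy/precision/recall/F1 use a 0.5 threshold with the first-named
   class group as positive.

Because no deep-learning framework ships with the package's dependency set,
the neural layers are implemented in a compact numpy core
(`expr2img.layers`): im2col + BLAS convolution, pooling with argmax
routing, inverted dropout, Adam, and a numerically stable
binary-cross-entropy-on-logits.  Everything runs in float32 and is
bit-reproducible for a fixed seed.

## Design choices where the design was open

* **Normalization axes.** "Standardize, then min–max to [0, 1]" leaves the
  axis unstated; both operations are applied per gene, the convention for
  expression arrays, and the per-dataset z-score is what removes the affine
  batch distortions the simulator plants.  Constant genes map to 0 in both
  steps (no NaNs).
* **LDA observation design.** "Map every gene into 2D" is only well-posed
  with genes as observations; a gene's feature vector is its expression
  profile across the training samples and its class is its Fisher
  category.
* **Fusion training regime.**  `FusionClassifier` supports end-to-end joint
  training from random initialization, warm-started fine-tuning, and the
  regime the evaluator uses by default: the two branches are trained first
  as standalone classifiers, their t-dimensional output vectors are frozen,
  standardized to the training-set scale, and the joint head alone is
  trained on the merged vectors.  Two reasons.  First, the architecture's
  own description — merge "the vectors of the output layers of the CNN and
  FNN", then train a joint network — reads most naturally as training the
  joint layers on the outputs of the already-trained branches, and the
  fusion model training *faster* than the CNN alone is only consistent with
  the convolutional weights not being retrained.  Second, at this package's
  desk scale, joint training from scratch under a small epoch budget is
  unstable: the randomly initialized head can latch onto whichever branch's
  features happen to descend faster, occasionally collapsing the fused
  model below its own better branch.  Pretrained-frozen branches with a
  scale-standardized concatenation remove both failure modes and are
  deterministic for a fixed seed.  The standardization of the merged vector
  is this package's own addition; without it the branch with the larger
  feature norms dominates the head's gradients.
* **Fold stratification.** Folds are stratified (plain disjoint subsets
  would risk single-class test folds at small n).
* **Per-fold refitting.** Selection, scoring and the map are refit inside
  every fold.  Fitting them once globally would leak test labels into the
  image layout; the cost is that each fold may select a different gene set.
* **Epoch cap.** The early-stop rule alone need not terminate (training
  loss can improve indefinitely), so an explicit `max_epochs` cap exists
  (default 2000).

## The synthetic cohort generator

`simdata` emulates a multi-dataset case/control expression study: Gaussian
per-gene noise (`noise_sd`, default 1.0), a designated subset of
informative genes whose class means are separated by `effect_size` latent
units (alternating which extreme class is shifted, so both up- and
down-regulated genes exist), MCI placed midway between NC and AD on every
informative gene, and a per-dataset affine batch effect (scale drawn from
`batch_scale_range`, offset from `batch_offset_range`) applied after the
signal.  Defaults (3 datasets × 50 samples per class, 1000 genes, 60
informative, effect 1.0, scale 0.8–1.2, offset ±0.5) give a cohort of 300
samples per two-class task — large enough for five-fold evaluation, small
enough for CPU training.

What the generator does *not* emulate: gene–gene correlation, probe
cross-hybridization, intensity-dependent variance, and platform-specific
distributional quirks.  Consequently, passing tests demonstrate that the
pipeline's machinery (selection, mapping, training, evaluation protocol)
behaves correctly and that planted signal is recovered and destroyed when
it should be — they do not certify classification performance on real
cohorts.

One consequence of the generator's independence assumption deserves
emphasis: genes with equal Fisher scores but *opposite* regulation
directions land in the same category and hence in nearby pixels, and
pixel-level averaging partially cancels their signal.  On real data,
co-discriminative genes are often co-regulated, so the cancellation is
milder.  At desk scale this makes the image branch systematically weaker
than the expression branch — the reverse of the relation reported on real
cohorts — and the fused model's headroom over the better branch is
therefore limited by how much of the (near-saturated) expression branch's
performance survives the merge.

## Numerical conventions

* Population (ddof = 0) standard deviations and variances throughout.
* Fisher ε-guard 1e-12; LASSO nonzero threshold 1e-12.
* Rectangle area ties broken by smallest rotation magnitude; rotation
  normalized into (−45°, 45°].
* Pixel rounding is half-up (`floor(x + 0.5)`), frozen for
  bit-reproducibility; image row 0 is the top.
* Images smaller than 8×8 are rejected (three 2× poolings need ≥ 8 pixels
  per side).
* All randomness flows from `numpy.random.default_rng(seed)`; per-fold,
  per-model training seeds are derived arithmetically from the master seed.

## Problem sizes used in the shipped evaluations

The test suite and the acceptance script run the full pipeline at a
12×12 image resolution on the 300-sample default cohort with training
capped at 60 epochs (early-stop warmup 20).  These sizes keep a complete
three-model five-fold evaluation within a few CPU-minutes while still
exercising pixel collisions, batch correction, and the early-stop rule.
The library default resolution is 50×50.

## Known limitations

* Gene images are single-channel; multi-channel or auto-tuned resolutions
  are out of scope.
* The LASSO λ default (1e-6) is extremely mild: on cohorts where samples
  are few and genes already number in the hundreds it may select nearly
  everything.  It reproduces the published operating point rather than an
  optimal one; `lambda_upper_bound` helps pick stronger penalties.
* Probe-to-symbol collapsing, platform normalization (RMA/quantile), and
  automatic GEO downloads are out of scope; series-matrix files are parsed
  from local disk.
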