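# Methods

This note documents the models and procedures implemented in
`celldistill`, the synthetic data they are exercised on, the parameters
that matter, and what the package's tests do and do not establish.

## Self-distillation objective

Training maintains a student and a teacher of identical architecture. Per
step, each image in the batch is expanded into `n_global` large crops
(default 2) and `n_local` small crops (default 4 for the 4-channel
protein-localization preset, 0 for the 5-channel profiling preset, where
local crops hurt at low resolution). The teacher runs on global views
only, without gradient tracking. Losses:

* **View-matching cross-entropy.** Teacher logits are centered by a
  running mean `c` and sharpened at temperature τ_t; student logits use
  τ_s. The loss averages H(P_t(v), P_s(u)) over ordered pairs with u ≠ v.
  Centering update: c ← m_c·c + (1−m_c)·batch-mean (m_c = 0.9).
* **Masked-patch (iBOT-style) loss** at patch tokens the student saw
  replaced by a learned mask token (one random rectangular block covering
  ≈ 30% of the grid, on the first global view of each image); the teacher
  saw the intact view. Patch logits keep their own center. The projection
  head is shared with the class-token head (a separate-head mode is a
  straightforward extension; sharing minimizes parameters at this scale).
* **KoLeo regularizer** on the student's global-view class tokens:
  −mean log(dᵢ + ε) with dᵢ the nearest-neighbour distance after L2
  normalization, weight λ_koleo = 0.1.

Teacher update: EMA with constant momentum m_ema = 0.996 at desk scale
(a cosine ramp toward 1.0 is the convention for long schedules; with a few
hundred steps a constant is the appropriate degenerate case). Optimizer:
AdamW (decoupled weight decay 0.04), linear warmup then cosine decay.

Temperatures, loss weights, masking scheme and schedule values are not
uniquely determined by the method description this package follows; they
are configuration with the defaults above (τ_s = 0.1, τ_t warmed linearly
0.04 → 0.07 over the first 100 steps), inherited from the published
self-distillation line. No claim of fidelity to any specific original run
is made.

Sinkhorn-style teacher normalization is not implemented; classic centering
only. That is a deliberate scope choice.

## Architecture

Channel-configurable ViT: C·p² pixels per patch are flattened and linearly
projected to width d; a class token is prepended; learned position
encodings are added; pre-norm transformer blocks follow. Patch order is
row-major, 0-based. At inference sizes other than the training size the
2-D position-encoding grid is interpolated bicubically (implemented as a
cached linear map, so it is differentiable and exact at the training
size). Initialization: truncated normal σ = 0.02, zero biases.

The embedding readout is concat(class token, mean over last-block patch
tokens) → length 2d. The projection head is a 3-layer MLP (d → hidden →
hidden → bottleneck), L2-normalization of the bottleneck, then a bias-free
prototype layer with K logits. Reference configuration: hidden 2048,
bottleneck 256, K = 65,536; desk configuration: hidden 256, bottleneck 64,
K = 1,024 to keep CPU runs fast. The evaluation MLP head consumes the
feature-wise concatenation of the last four layers' patch tokens (D = 4d)
through learned-query attention pooling and a hidden layer of size 4d —
4096 for a width-1024 backbone. (Concatenating token *sequences* instead
of features is the other reading of that construction; feature-wise
concatenation is the one consistent with a 4d hidden layer.)

### The autodiff core

No deep-learning framework is used. `celldistill.nn` is a reverse-mode
autodiff on float64 numpy arrays: a `Tensor` records primitive operations
with hand-written vector-Jacobian products and `backward()` walks the tape
in reverse topological order. Every primitive and the composite layers are
checked against central differences in `tests/test_nn.py`. Float64 and
single-process execution make training traces and feature tables exactly
reproducible for a fixed seed.

## Synthetic scenes

The generator renders what the pipelines need and nothing more:

* Cells are anisotropic elliptical blobs (nucleus = concentric ellipse at
  0.52 of the cell axes); morphology factors set the axes as fractions of
  the scene size, emulating cell-line differences. Rejection sampling
  places non-overlapping centres; impossible requests raise a placement
  error.
* Channels: a nucleus dye (Gaussian falloff inside the nucleus),
  structural dyes (cell-body falloffs with multiplicative speckle), and a
  protein channel painted by localization class — nuclear (nuclear blob),
  nucleoplasm (flat fill), cytoplasm (cell minus nucleus), membrane
  (elliptical ring), punctate (Poisson-placed small Gaussians), negative
  (nothing). Background level and Gaussian pixel noise are added, then
  values are clipped to [0, 1]; rasters are written as 16-bit TIFF.
* Heterogeneity modes: *spatial* re-draws each cell's class with
  probability 0.5 to a fixed alternate class (one consistent second
  pattern per condition, as a heterogeneous protein would show); or
  *intensity* scales each cell's protein gain log-uniformly in
  [0.25, 1].
* Batch effects: per-channel gain/offset (`clip(g·x + b)`) at the image
  level, and — for the batch-correction protocol — additive per-batch
  offset vectors at the profile level (see below).
* Determinism: one root seed; per-image streams are derived by hashing
  (seed, image_id), so dataset generation is order-independent.

What the generator does **not** emulate: point-spread-function optics,
3-D structure, realistic texture, cell-cycle or density variation,
segmentation errors. Passing the tests below shows the algorithms behave
as specified on data with clean class structure; it does not certify
performance numbers on real microscopy.

### Profile-level batch-correction substrate

The sphering ablation operates on well-level profiles generated directly
in feature space: 4 mechanism groups × 6 treatments × 3 wells, treatments
sharing a group direction plus treatment jitter; 6 batches contribute
additive offset vectors (scale 1.5 vs. effect scale 1.0) with batch
membership drawn independently of mechanism; 12 control wells per batch
carry offset plus noise only. Profile-level injection is used because the
image pipeline's per-channel self-normalization is affine-invariant and
would erase pure gain/offset image effects before they reach the
embedding. Two layout choices matter and were fixed after diagnosing
degenerate behaviour: batch membership must be independent of mechanism
(otherwise offsets leak class signal and *help* the uncorrected branch),
and the control count must exceed the feature dimension (72 controls, 32
features) so the control covariance is full rank — a rank-deficient fit
amplifies null-space noise under whitening.

## Profiling and evaluation

* Aggregation is the arithmetic mean per field of view → well →
  treatment, with `n_members` recorded and metadata carried when constant
  within a group.
* Sphering is ZCA: W = V(Λ+λI)^(−1/2)Vᵀ with λ defaulting to 1e-6 × mean
  eigenvalue, fit on negative-control wells (configurable to all wells),
  applied to well-level rows before treatment aggregation. ZCA rather
  than PCA whitening keeps features in their original orientation. The fit
  is global rather than per-plate by default; per-plate fitting is a
  caller-side loop.
* Similarity matrices are cosine with unit diagonal; zero-norm rows are
  flagged and set to zero similarity. Matrix ordering uses average-linkage
  hierarchical clustering on 1 − S (scipy's deterministic merge order).
* kNN: cosine similarity, k = 20, vote weight exp(sim/τ) with τ = 0.07,
  ties to the lowest class index.
* Multilabel calibration: per-class threshold maximizing F1 over the grid
  0.00–1.00 step 0.01, ties to the lowest threshold; classes without
  positives get threshold 1.0 and a flag. Fold ensembling averages scores
  and thresholds. Macro F1 counts a class with neither true nor predicted
  positives as 1.0 (configurable); the convention is recorded because it
  matters for rare classes.
* MoA retrieval: one-vs-rest L2-regularized logistic models,
  stratified 5-fold cross-validation, 10 repeats, scored by step-wise
  (interpolation-free) average precision, averaged over classes and
  repeats; classes with fewer positives than folds are excluded with a
  warning.
* Low-shot curves subsample ⌈frac·n⌉ rows per class (never below one),
  train a probe on frozen features, and report macro F1 on a fixed
  held-out split.

## Single-cell heterogeneity statistic

Pooled single-cell embeddings of one condition are compared by cosine
similarity; the matrix is cut by average-linkage clustering into at most 4
clusters; clusters holding ≥ 20% of cells count as blocks, and the
statistic is mean within-block minus between-block similarity (0 when
fewer than two blocks form). The figure-style analysis is qualitative;
this surrogate makes it testable. Two robustness choices are load-bearing:
small clusters are outliers rather than blocks (a 3-of-30 straggler
cluster otherwise dominates), and per-cell crops are exactly centred via
reflect padding (border clamping otherwise creates a spurious "edge cell"
block). The decision threshold is 0.1.

## Desk-scale study conditions and problem sizes

The reference experiments (shared by `tests/` and `scripts/acceptance.py`)
use: 32×32 4-channel scenes, 2 cells per scene, four localization classes
(nuclear, cytoplasm, membrane, punctate), 2,000 training and 400 held-out
images; a width-32, depth-2, 4-head ViT with patch size 8; 700
optimisation steps at batch 16 (the longer end of the ≥ 300-step regime:
by 300 steps the kNN gain is already large, but class geometry keeps
tightening through ~700, which the heterogeneity analysis relies on);
heterogeneity conditions render 30 single-cell 64×64 scenes per seed.
These sizes keep every experiment within minutes on one CPU while leaving
the qualitative conclusions stable across seeds.

## Known limitations

* Evidence is synthetic and desk-scale; none of the reported numbers are
  comparable to benchmark results on real HPA or Cell Painting data.
* The supervised baseline used in the label-efficiency comparison is a
  plain ViT + linear head without augmentation-tuning or schedule
  searches; it bounds what "from scratch on 1% of labels" can do at this
  scale, not what a tuned supervised pipeline could.
* Single-GPU/CPU single-process only; no mixed precision, no distributed
  training.
* Harmony-style embedding integration is out of scope; the profiling
  tables keep a `batch` column so such tools can be applied downstream.
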