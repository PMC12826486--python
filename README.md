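# celldistill

Self-distillation representation learning and image-based profiling for
multi-channel fluorescence microscopy, in pure scientific Python.

Microscopy screens produce far more images than anyone can annotate:
protein-localization atlases label a handful of subcellular patterns, and
Cell Painting compound screens have almost no per-image labels at all.
`celldistill` implements the self-supervised route around that bottleneck: a
channel-configurable vision transformer (ViT) is trained as a
student/teacher pair without any labels, and its frozen features are then
used for everything downstream — classification probes, nearest-neighbour
retrieval, well- and treatment-level profiling with batch correction, and
single-cell heterogeneity analysis.

## The method

Two architecturally identical networks process random views of the same
image. The **teacher** sees large "global" crops; the **student** sees
global and small "local" crops. Both map each view through a projection
head to a distribution over K prototypes, and the student is trained with
the cross-entropy

  H(P_t(v), P_s(u)),  P_t = softmax((t − c)/τ_t),  P_s = softmax(s/τ_s)

averaged over ordered view pairs (u ≠ v). The teacher receives no
gradients; its weights are an exponential moving average of the student,
θ_t ← m·θ_t + (1−m)·θ_s. The running center c (momentum mean of teacher
logits) plus the sharp teacher temperature τ_t < τ_s prevents collapse onto
a single prototype. Two auxiliary terms are added: a **KoLeo** regularizer
−mean_i log d_i (d_i = nearest-neighbour distance of the L2-normalized
class-token embeddings) that spreads features apart, and an **iBOT-style
masked-patch loss** — the student sees a block of patch tokens replaced by
a mask token and must match the teacher's distribution at those positions.

Augmentations are the ones appropriate for fluorescence channels: random
resized crops, flips, per-channel brightness/contrast jitter, random
rescaling of the protein channel, and zeroing one randomly chosen channel.
Blur, solarization and greyscale are deliberately absent. Every view ends
with per-channel self-normalization (x − mean)/std.

After training, the projection head is dropped and an image is represented
by concat(class token, mean of patch tokens) — a vector of length exactly
2·width (2048 for a width-1024 ViT). Profiles are built by averaging
embeddings per field of view → well → treatment; **sphering** (ZCA
whitening fit on negative-control wells, x′ = W(x − μ) with
W = V(Λ+λI)^(−1/2)Vᵀ) is applied to well-level profiles before treatment
aggregation to remove plate-level batch effects.

There is no dependency on a deep-learning framework: a compact reverse-mode
autodiff core on numpy (`celldistill.nn`) provides the tensors, layers and
AdamW used by the training loop, with gradients verified against central
differences in the test suite.

## Worked example

```python
import numpy as np
import celldistill as cd
from celldistill import protocols

# 2,000 training + 400 held-out 4-class localization scenes (32x32, 4ch)
train_imgs, train_y, test_imgs, test_y = protocols.default_corpus()

# self-distillation, width-32 depth-2 ViT, 700 steps (~2 min on one CPU)
run = protocols.training_signal_experiment(seed=0)
print(f"kNN accuracy  trained: {run['ssl_accuracy']:.3f}  "
      f"random init: {run['random_accuracy']:.3f}  "
      f"gain: {run['gain_points']:.1f} points")
```

Output from this exact snippet:

```
kNN accuracy  trained: 0.858  random init: 0.613  gain: 24.5 points
```

The trained teacher's frozen features classify held-out scenes at 85.8%
with a 20-nearest-neighbour cosine vote, 24.5 points above an untrained
backbone of identical architecture — the label-free training signal the
method is built around. The batch-correction ablation runs the same way:

```python
res = protocols.batch_correction_experiment(seed=0)
print(f"MoA retrieval with sphering {res['with_bc']:.2f}, "
      f"without {res['without_bc']:.2f} ({res['percent_change']:+.1f}%)")
# MoA retrieval with sphering 0.53, without 0.44 (-18.7%)
```

Skipping the whitening step costs roughly a fifth of the retrieval score
— batch effects are real signal to the embedding and must be removed.

## Command line

```bash
celldistill simulate --plan plan.yaml --out data/ --seed 1
celldistill train    --config run.yaml --data data/ --out model.ckpt
celldistill embed    --ckpt model.ckpt --index data/index.csv --crop 32 --out emb
celldistill profile  --embeddings emb --level treatment --sphering controls --out prof
celldistill evaluate --embeddings emb --task knn --out report.json
celldistill inspect  --ckpt model.ckpt --index data/index.csv --mode pca --out maps/
```

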