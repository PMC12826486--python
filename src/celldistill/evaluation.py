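"""Label-using evaluations of frozen representations.

Implements the downstream protocols used to score embeddings: linear probes
and attention-pooled MLP heads on frozen features, per-class threshold
calibration with fold ensembling for multilabel tasks, temperature-weighted
cosine kNN, macro F1, cross-validated mechanism-of-action retrieval scored
by mean average precision, and low-shot label-fraction curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

from . import nn
from .errors import ConfigurationError

THRESHOLD_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 2)


# ---------------------------------------------------------------------------
# pooling and heads
# ---------------------------------------------------------------------------

def attention_pool(tokens: np.ndarray, query: np.ndarray) -> np.ndarray:
    """w = softmax(<token_i, q>/sqrt(D)); returns the weighted token sum."""
    tokens = np.asarray(tokens, dtype=np.float64)
    query = np.asarray(query, dtype=np.float64)
    d = tokens.shape[-1]
    scores = tokens @ query / np.sqrt(d)
    scores -= scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    return np.einsum("...n,...nd->...d", w, tokens)


class AttentionPoolMLP(nn.Module):
    """2-layer classification head with learned-query attention pooling.

    Consumes per-token features of dimension D (typically the feature-wise
    concatenation of the last 4 layers' patch tokens, D = 4*width) and emits
    per-class logits; the hidden layer defaults to 4 * backbone width.
    """

    def __init__(self, d_tokens: int, n_classes: int, hidden: int | None = None,
                 seed: int = 0):
        super().__init__()
        if hidden is None:
            # 4-layer feature-wise concatenation: hidden = 4 * backbone width
            hidden = d_tokens
        if hidden <= 0:
            raise ConfigurationError("hidden size must be positive")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
        self.d = d_tokens
        self.register("query", nn.trunc_normal(rng, (d_tokens,)))
        self.register("fc1", nn.Linear(d_tokens, hidden, rng))
        self.register("fc2", nn.Linear(hidden, n_classes, rng))

    def forward(self, tokens: np.ndarray) -> nn.Tensor:
        t = nn.Tensor(tokens)  # (B, N, D)
        scores = (t @ self.query) * (1.0 / np.sqrt(self.d))
        w = nn.softmax(scores, axis=-1)  # (B, N)
        b, n, d = t.shape
        pooled = (w.reshape(b, 1, n) @ t).reshape(b, d)
        return self.fc2(self.fc1(pooled).gelu())


def train_mlp_head(token_features: np.ndarray, labels: np.ndarray, hidden: int,
                   n_steps: int = 200, lr: float = 1e-3, batch_size: int = 32,
                   seed: int = 0) -> AttentionPoolMLP:
    """Train an attention-pooled MLP head with per-class sigmoid outputs."""
    labels = np.asarray(labels, dtype=np.float64)
    head = AttentionPoolMLP(token_features.shape[-1], labels.shape[1], hidden, seed)
    opt = nn.AdamW(head.parameters(), lr=lr, weight_decay=0.01)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    n = len(token_features)
    for _ in range(n_steps):
        idx = rng.integers(0, n, size=min(batch_size, n))
        logits = head(token_features[idx])
        y = nn.Tensor(labels[idx])
        # sigmoid binary cross-entropy via the softplus identity
        loss = ((1.0 - y) * logits + (1.0 + (-logits).exp()).log()).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    return head


# ---------------------------------------------------------------------------
# probes
# ---------------------------------------------------------------------------

def stratified_subsample(labels: np.ndarray, frac: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Indices of a per-class subsample of size ceil(frac * n_class) each.

    For multilabel matrices the subsample guarantees at least one positive
    example per class with any positives at all.
    """
    if not 0 < frac <= 1:
        raise ConfigurationError("frac must be in (0, 1]")
    labels = np.asarray(labels)
    chosen: set[int] = set()
    if labels.ndim == 1:
        for c in np.unique(labels):
            idx = np.nonzero(labels == c)[0]
            k = int(np.ceil(frac * len(idx)))
            chosen.update(rng.choice(idx, size=k, replace=False).tolist())
    else:
        for c in range(labels.shape[1]):
            idx = np.nonzero(labels[:, c] > 0)[0]
            if len(idx) == 0:
                continue
            k = int(np.ceil(frac * len(idx)))
            chosen.update(rng.choice(idx, size=k, replace=False).tolist())
    return np.sort(np.fromiter(chosen, dtype=int))


@dataclass
class Probe:
    """Frozen-feature classifier: a head trained on embeddings only."""

    kind: str
    models: list = field(default_factory=list)
    classes: np.ndarray | None = None
    multilabel: bool = False

    def scores(self, x: np.ndarray) -> np.ndarray:
        if self.multilabel:
            cols = []
            for m in self.models:
                if m is None:
                    cols.append(np.zeros(len(x)))
                else:
                    cols.append(m.predict_proba(x)[:, 1])
            return np.column_stack(cols)
        return self.models[0].predict_proba(x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.multilabel:
            return (self.scores(x) >= 0.5).astype(int)
        return self.classes[self.scores(x).argmax(axis=1)]


def train_probe(features: np.ndarray, labels: np.ndarray, head: str = "linear",
                frac: float = 1.0, seed: int = 0, max_iter: int = 500) -> Probe:
    """Train a classifier head on frozen features.

    Single-label targets (1-D ``labels``) get a multinomial softmax linear
    model; multilabel binary matrices get independent per-class sigmoid
    models.  ``frac`` subsamples the training rows stratified per class.
    """
    if head != "linear":
        raise ConfigurationError("train_probe heads: 'linear' (MLP heads are "
                                 "trained via train_mlp_head on token maps)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    labels = np.asarray(labels)
    idx = stratified_subsample(labels, frac, rng) if frac < 1.0 \
        else np.arange(len(labels))
    x, y = np.asarray(features)[idx], labels[idx]
    if y.ndim == 1:
        clf = LogisticRegression(max_iter=max_iter, C=1.0)
        clf.fit(x, y)
        return Probe("linear", [clf], classes=clf.classes_, multilabel=False)
    models = []
    for c in range(y.shape[1]):
        col = y[:, c]
        if len(np.unique(col)) < 2:
            warnings.warn(f"class {c} has a single label value in the training set; dropped")
            models.append(None)
            continue
        clf = LogisticRegression(max_iter=max_iter, C=1.0)
        clf.fit(x, col)
        models.append(clf)
    return Probe("linear", models, multilabel=True)


# ---------------------------------------------------------------------------
# thresholds, ensembling, metrics
# ---------------------------------------------------------------------------

def _binary_f1(pred: np.ndarray, true: np.ndarray, empty_value: float = 1.0) -> float:
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    if tp + fp + fn == 0:
        return empty_value
    return 2.0 * tp / (2.0 * tp + fp + fn)


def best_threshold_per_class(scores: np.ndarray, labels: np.ndarray,
                             grid: np.ndarray = THRESHOLD_GRID
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-class threshold maximizing F1 over the grid (ties -> lowest).

    Classes without positive labels get threshold 1.0 and are flagged.
    Returns (thresholds, flagged boolean vector).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_classes = scores.shape[1]
    thresholds = np.ones(n_classes)
    flagged = np.zeros(n_classes, dtype=bool)
    for c in range(n_classes):
        true = labels[:, c]
        if not true.any():
            flagged[c] = True
            continue
        best_f1, best_t = -1.0, 1.0
        for t in grid:
            f1 = _binary_f1(scores[:, c] >= t, true, empty_value=0.0)
            if f1 > best_f1:  # strict: ties keep the lowest threshold
                best_f1, best_t = f1, t
        thresholds[c] = best_t
    return thresholds, flagged


def ensemble_predict(head_scores: list[np.ndarray],
                     thresholds: list[np.ndarray]) -> np.ndarray:
    """Prediction and threshold averaging across folds/heads."""
    score = np.mean(head_scores, axis=0)
    thr = np.mean(thresholds, axis=0)
    return (score >= thr).astype(int)


def macro_f1(pred: np.ndarray, true: np.ndarray, empty_value: float = 1.0) -> float:
    """Unweighted mean of per-class F1.

    A class with neither true nor predicted positives contributes
    ``empty_value`` (default 1: the classifier was right to stay silent).
    """
    pred = np.asarray(pred).astype(bool)
    true = np.asarray(true).astype(bool)
    if pred.ndim == 1:
        pred, true = pred[:, None], true[:, None]
    return float(np.mean([_binary_f1(pred[:, c], true[:, c], empty_value)
                          for c in range(pred.shape[1])]))


def single_label_macro_f1(pred: np.ndarray, true: np.ndarray) -> float:
    """Macro F1 of single-label predictions, over the union of classes."""
    classes = np.unique(np.concatenate([np.asarray(pred), np.asarray(true)]))
    p = np.column_stack([np.asarray(pred) == c for c in classes])
    t = np.column_stack([np.asarray(true) == c for c in classes])
    return macro_f1(p, t)


# ---------------------------------------------------------------------------
# kNN
# ---------------------------------------------------------------------------

def knn_classify(train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray,
                 k: int = 20, tau: float = 0.07) -> np.ndarray:
    """Cosine kNN with vote weights exp(similarity / tau); ties -> lowest class.

    Labels are integer class indices; k is clamped to the training size.
    """
    train_x = np.asarray(train_x, dtype=np.float64)
    test_x = np.asarray(test_x, dtype=np.float64)
    train_y = np.asarray(train_y)
    if k > len(train_x):
        warnings.warn(f"k={k} exceeds training size {len(train_x)}; clamped")
        k = len(train_x)
    tn = train_x / np.maximum(np.linalg.norm(train_x, axis=1, keepdims=True), 1e-12)
    qn = test_x / np.maximum(np.linalg.norm(test_x, axis=1, keepdims=True), 1e-12)
    sims = qn @ tn.T
    classes = np.unique(train_y)
    out = np.empty(len(test_x), dtype=classes.dtype)
    for i in range(len(test_x)):
        nbr = np.argsort(-sims[i], kind="stable")[:k]
        w = np.exp(sims[i, nbr] / tau)
        votes = np.zeros(len(classes))
        for j, c in enumerate(classes):
            votes[j] = w[train_y[nbr] == c].sum()
        out[i] = classes[int(np.argmax(votes))]  # argmax takes lowest on ties
    return out


# ---------------------------------------------------------------------------
# MoA retrieval
# ---------------------------------------------------------------------------

def moa_auprc(profiles: np.ndarray, moa_labels: np.ndarray, n_folds: int = 5,
              n_repeats: int = 10, seed: int = 0, max_iter: int = 500) -> dict:
    """Cross-validated one-vs-rest mechanism retrieval scored by mean AP.

    ``moa_labels`` is a binary (n, K) multilabel matrix (a 1-D class vector
    is accepted and one-hot encoded).  Per repeat: stratify k folds, train
    an L2-regularized linear model per class, collect held-out scores, and
    average the step-wise average precision over classes.  Classes with
    fewer positives than folds are excluded with a warning.
    """
    x = np.asarray(profiles, dtype=np.float64)
    y = np.asarray(moa_labels)
    if y.ndim == 1:
        classes = np.unique(y)
        y = np.column_stack([(y == c).astype(int) for c in classes])
    keep = y.sum(axis=0) >= n_folds
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} classes with < {n_folds} positives")
    y = y[:, keep]
    if y.shape[1] == 0:
        raise ConfigurationError("no class has enough positives for cross-validation")

    strat = np.array(["|".join(map(str, row)) for row in y])
    repeat_means = []
    per_class = np.zeros(y.shape[1])
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed * 1000 + rep)
        scores = np.zeros_like(y, dtype=np.float64)
        try:
            splits = list(skf.split(x, strat))
        except ValueError:  # rare label combinations: fall back to plain folds
            rng = np.random.default_rng(seed * 1000 + rep)
            order = rng.permutation(len(x))
            splits = [(np.setdiff1d(order, chunk), chunk)
                      for chunk in np.array_split(order, n_folds)]
        for tr, te in splits:
            for c in range(y.shape[1]):
                if len(np.unique(y[tr, c])) < 2:
                    continue
                clf = LogisticRegression(max_iter=max_iter, C=1.0)
                clf.fit(x[tr], y[tr, c])
                scores[te, c] = clf.predict_proba(x[te])[:, 1]
        aps = np.array([average_precision_score(y[:, c], scores[:, c])
                        for c in range(y.shape[1])])
        per_class += aps
        repeat_means.append(float(aps.mean()))
    return {"mean_auprc": float(np.mean(repeat_means)),
            "sd": float(np.std(repeat_means)),
            "per_class": per_class / n_repeats,
            "n_classes": int(y.shape[1]), "n_repeats": n_repeats}


# ---------------------------------------------------------------------------
# low-shot protocol
# ---------------------------------------------------------------------------

def low_shot_protocol(features: np.ndarray, labels: np.ndarray,
                      test_features: np.ndarray, test_labels: np.ndarray,
                      fractions=(0.01, 0.1, 0.5, 1.0), seeds=(0, 1, 2)) -> pd.DataFrame:
    """Macro-F1 curve over label fractions on a fixed held-out split."""
    rows = []
    for frac in fractions:
        for seed in seeds:
            probe = train_probe(features, labels, frac=frac, seed=seed)
            pred = probe.predict(test_features)
            if np.asarray(labels).ndim == 1:
                f1 = single_label_macro_f1(pred, test_labels)
            else:
                f1 = macro_f1(pred, test_labels)
            rows.append({"fraction": frac, "seed": seed, "macro_f1": f1})
    df = pd.DataFrame(rows)
    return df.groupby("fraction", as_index=False).agg(
        mean_f1=("macro_f1", "mean"), sd_f1=("macro_f1", "std"))
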