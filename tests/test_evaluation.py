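"""Evaluation protocols against brute-force oracles, plus the low-shot
frozen-feature-vs-supervised property."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celldistill.evaluation import (THRESHOLD_GRID, AttentionPoolMLP,
                                    attention_pool, best_threshold_per_class,
                                    ensemble_predict, knn_classify,
                                    low_shot_protocol, macro_f1, moa_auprc,
                                    single_label_macro_f1,
                                    stratified_subsample, train_mlp_head,
                                    train_probe)

# -- attention pooling -------------------------------------------------------

def test_attention_pool_identical_tokens_returns_that_token(rng):
    token = rng.normal(size=5)
    tokens = np.tile(token, (7, 1))
    out = attention_pool(tokens, rng.normal(size=5))
    assert np.allclose(out, token)


def test_attention_pool_single_token_is_identity(rng):
    token = rng.normal(size=(1, 4))
    assert np.allclose(attention_pool(token, rng.normal(size=4)), token[0])


def test_attention_pool_two_token_hand_case():
    tokens = np.array([[1.0, 0.0], [0.0, 1.0]])
    query = np.array([2.0, 0.0])
    scores = tokens @ query / np.sqrt(2)
    w = np.exp(scores) / np.exp(scores).sum()
    expected = w[0] * tokens[0] + w[1] * tokens[1]
    assert np.allclose(attention_pool(tokens, query), expected, atol=1e-12)


def test_attention_mlp_hidden_dimension(rng):
    head = AttentionPoolMLP(d_tokens=8, n_classes=3, hidden=32)
    assert head.fc1.weight.shape == (8, 32)
    out = head(rng.normal(size=(2, 5, 8)))
    assert out.shape == (2, 3)


def test_mlp_head_learns_separable_tokens(rng):
    # class decided by the mean token direction
    n = 40
    labels = np.zeros((n, 2))
    tokens = rng.normal(size=(n, 6, 4)) * 0.1
    for i in range(n):
        c = i % 2
        labels[i, c] = 1
        tokens[i] += np.eye(4)[c] * 2
    head = train_mlp_head(tokens, labels, hidden=16, n_steps=300, seed=0)
    pred = (head(tokens).data > 0).astype(int)
    assert (pred == labels).mean() > 0.95


# -- probes ------------------------------------------------------------------

def test_probe_perfect_on_separable_embeddings(rng):
    x = np.vstack([rng.normal(size=(20, 3)) + [5, 0, 0],
                   rng.normal(size=(20, 3)) - [5, 0, 0]])
    y = np.array([0] * 20 + [1] * 20)
    probe = train_probe(x, y)
    assert (probe.predict(x) == y).mean() == 1.0


def test_probe_multilabel_uses_per_class_sigmoids(rng):
    x = rng.normal(size=(30, 4))
    y = np.zeros((30, 2), dtype=int)
    y[x[:, 0] > 0, 0] = 1
    y[x[:, 1] > 0, 1] = 1
    probe = train_probe(x, y)
    assert probe.multilabel
    scores = probe.scores(x)
    assert scores.shape == (30, 2)
    assert np.all((scores >= 0) & (scores <= 1))


def test_probe_linear_head_parameter_count(rng):
    d2, k = 6, 3  # embedding length 2d = 6
    x = rng.normal(size=(60, d2))
    y = rng.integers(0, k, size=60)
    probe = train_probe(x, y)
    clf = probe.models[0]
    n_params = clf.coef_.size + clf.intercept_.size
    assert n_params == (d2 + 1) * k


def test_stratified_subsample_sizes_are_ceil_frac_n(rng):
    y = np.array([0] * 50 + [1] * 30 + [2] * 20)
    idx = stratified_subsample(y, 0.1, rng)
    _, counts = np.unique(y[idx], return_counts=True)
    assert list(counts) == [5, 3, 2]
    idx = stratified_subsample(y, 0.01, rng)
    _, counts = np.unique(y[idx], return_counts=True)
    assert list(counts) == [1, 1, 1]  # at least one example per class


# -- thresholds and ensembling ----------------------------------------------

def test_best_threshold_perfectly_separated_reaches_f1_one():
    scores = np.array([[0.9], [0.8], [0.2], [0.1]])
    labels = np.array([[1], [1], [0], [0]])
    thr, flagged = best_threshold_per_class(scores, labels)
    pred = scores[:, 0] >= thr[0]
    assert macro_f1(pred, labels[:, 0]) == 1.0
    assert not flagged[0]


def test_best_threshold_four_sample_toy_lands_between_negatives_and_positives():
    scores = np.array([[0.9], [0.7], [0.4], [0.1]])
    labels = np.array([[1], [1], [0], [0]])
    thr, _ = best_threshold_per_class(scores, labels)
    assert 0.4 < thr[0] <= 0.7


def test_best_threshold_all_negative_class_flagged():
    scores = np.array([[0.9], [0.1]])
    labels = np.array([[0], [0]])
    thr, flagged = best_threshold_per_class(scores, labels)
    assert thr[0] == 1.0 and flagged[0]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_threshold_search_equals_exhaustive_grid(seed):
    """Oracle equivalence on random instances: per class, the implementation
    returns the lowest grid threshold attaining the maximal F1."""
    rng = np.random.default_rng(seed)
    scores = rng.uniform(size=(12, 3))
    labels = rng.integers(0, 2, size=(12, 3))
    thr, flagged = best_threshold_per_class(scores, labels)
    for c in range(3):
        if flagged[c]:
            assert labels[:, c].sum() == 0
            continue
        true = labels[:, c].astype(bool)
        f1s = []
        for t in THRESHOLD_GRID:
            pred = scores[:, c] >= t
            tp = (pred & true).sum()
            fp = (pred & ~true).sum()
            fn = (~pred & true).sum()
            f1s.append(0.0 if tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn))
        f1s = np.array(f1s)
        best = THRESHOLD_GRID[np.flatnonzero(f1s == f1s.max())[0]]
        assert thr[c] == best


def test_ensemble_single_head_reduces_to_plain_thresholding(rng):
    scores = rng.uniform(size=(10, 3))
    thr = rng.uniform(size=3)
    assert np.array_equal(ensemble_predict([scores], [thr]),
                          (scores >= thr).astype(int))


def test_ensemble_identical_heads_match_single_head(rng):
    scores = rng.uniform(size=(10, 3))
    thr = rng.uniform(size=3)
    a = ensemble_predict([scores, scores, scores], [thr, thr, thr])
    assert np.array_equal(a, ensemble_predict([scores], [thr]))


def test_ensemble_two_head_hand_case():
    s1 = np.array([[0.8, 0.2]])
    s2 = np.array([[0.4, 0.6]])
    t1 = np.array([0.5, 0.5])
    t2 = np.array([0.7, 0.3])
    # mean score (0.6, 0.4) vs mean threshold (0.6, 0.4): >= wins both
    assert np.array_equal(ensemble_predict([s1, s2], [t1, t2]), [[1, 1]])


# -- macro F1 ----------------------------------------------------------------

def test_macro_f1_identities():
    y = np.array([[1, 0], [0, 1], [1, 1]])
    assert macro_f1(y, y) == 1.0
    assert macro_f1(y, 1 - y) == 0.0


def test_macro_f1_printed_confusion_case():
    # single class with TP=2, FP=1, FN=1: F1 = 2*2/(2*2+1+1) = 2/3
    pred = np.array([1, 1, 1, 0, 0])
    true = np.array([1, 1, 0, 1, 0])
    assert macro_f1(pred, true) == pytest.approx(2 / 3)


def test_macro_f1_empty_class_convention_is_configurable():
    pred = np.array([[1, 0], [0, 0]])
    true = np.array([[1, 0], [0, 0]])
    assert macro_f1(pred, true, empty_value=1.0) == 1.0
    assert macro_f1(pred, true, empty_value=0.0) == 0.5


# -- kNN ---------------------------------------------------------------------

def test_knn_duplicate_of_train_point_k1(rng):
    x = rng.normal(size=(10, 4))
    y = np.arange(10)
    pred = knn_classify(x, y, x[[3]], k=1)
    assert pred[0] == 3


def test_knn_three_point_hand_vote():
    train = np.array([[1.0, 0.0], [0.9, 0.1], [0.0, 1.0]])
    labels = np.array([0, 0, 1])
    pred = knn_classify(train, labels, np.array([[1.0, 0.05]]), k=3)
    assert pred[0] == 0  # two close class-0 neighbours outvote one far class-1


def test_knn_duplicating_training_set_leaves_predictions_unchanged(rng):
    x = rng.normal(size=(30, 5))
    y = rng.integers(0, 3, size=30)
    q = rng.normal(size=(8, 5))
    a = knn_classify(x, y, q, k=5)
    b = knn_classify(np.vstack([x, x]), np.concatenate([y, y]), q, k=10)
    assert np.array_equal(a, b)


def test_knn_clamps_k_with_warning(rng):
    x = rng.normal(size=(4, 3))
    y = np.array([0, 0, 1, 1])
    with pytest.warns(UserWarning, match="clamped"):
        knn_classify(x, y, x, k=50)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_knn_equals_exhaustive_brute_force(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(60, 4))
    y = rng.integers(0, 3, size=60)
    q = rng.normal(size=(10, 4))
    k, tau = 7, 0.07
    pred = knn_classify(x, y, q, k=k, tau=tau)
    xn = x / np.linalg.norm(x, axis=1, keepdims=True)
    qn = q / np.linalg.norm(q, axis=1, keepdims=True)
    for i in range(len(q)):
        sims = qn[i] @ xn.T
        nbr = np.argsort(-sims, kind="stable")[:k]
        votes = np.zeros(3)
        for j in nbr:
            votes[y[j]] += np.exp(sims[j] / tau)
        assert pred[i] == votes.argmax()


# -- average precision / MoA -------------------------------------------------

def stepwise_ap_oracle(labels, scores):
    """Brute-force enumeration of precision/recall steps (no interpolation)."""
    order = np.argsort(-scores, kind="stable")
    labels = np.asarray(labels)[order]
    tp, ap = 0, 0.0
    n_pos = labels.sum()
    for i, lab in enumerate(labels, start=1):
        if lab:
            tp += 1
            ap += (tp / i) / n_pos
    return ap


def test_ap_four_item_toy_hand_enumeration():
    from sklearn.metrics import average_precision_score

    labels = np.array([1, 0, 1, 0])
    scores = np.array([0.9, 0.8, 0.6, 0.2])
    # ranked: 1,0,1,0 -> AP = (1/1 + 2/3)/2 = 5/6
    assert average_precision_score(labels, scores) == pytest.approx(5 / 6)
    assert stepwise_ap_oracle(labels, scores) == pytest.approx(5 / 6)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(5, 20))
def test_ap_equals_stepwise_enumeration(seed, n):
    from sklearn.metrics import average_precision_score

    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=n)
    if labels.sum() == 0:
        labels[0] = 1
    scores = rng.uniform(size=n)
    assert average_precision_score(labels, scores) == pytest.approx(
        stepwise_ap_oracle(labels, scores), abs=1e-12)


def test_random_scores_ap_approaches_prevalence(rng):
    # balanced binary labels: mean AP over random rankings ~ prevalence 0.5
    # (finite-n bias decays with list length, hence n = 400)
    labels = np.array([1, 0] * 200)
    aps = [stepwise_ap_oracle(labels, rng.uniform(size=400)) for _ in range(1000)]
    assert np.mean(aps) == pytest.approx(0.5, abs=0.03)


def test_moa_auprc_perfectly_separable_profiles(rng):
    x = np.concatenate([rng.normal(size=(10, 4)) + 8 * np.eye(4)[i % 4]
                        for i in range(4)])
    y = np.repeat([f"m{i}" for i in range(4)], 10)
    res = moa_auprc(x, y, n_folds=5, n_repeats=2, seed=0)
    assert res["mean_auprc"] > 0.95
    assert res["n_classes"] == 4


def test_moa_auprc_excludes_rare_classes(rng):
    x = rng.normal(size=(22, 3))
    y = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 2)
    with pytest.warns(UserWarning, match="excluding"):
        res = moa_auprc(x, y, n_folds=5, n_repeats=1, seed=0)
    assert res["n_classes"] == 2


# -- low-shot ----------------------------------------------------------------

def test_low_shot_fraction_one_equals_plain_probe(rng):
    x = np.vstack([rng.normal(size=(25, 3)) + [4, 0, 0],
                   rng.normal(size=(25, 3)) - [4, 0, 0]])
    y = np.array([0] * 25 + [1] * 25)
    xt = np.vstack([rng.normal(size=(10, 3)) + [4, 0, 0],
                    rng.normal(size=(10, 3)) - [4, 0, 0]])
    yt = np.array([0] * 10 + [1] * 10)
    curve = low_shot_protocol(x, y, xt, yt, fractions=(1.0,), seeds=(0,))
    probe = train_probe(x, y, frac=1.0, seed=0)
    direct = single_label_macro_f1(probe.predict(xt), yt)
    assert curve["mean_f1"].iloc[0] == pytest.approx(direct)


def test_ssl_probe_beats_supervised_from_scratch_at_one_percent(ssl_runs, corpus):
    """Label-efficiency property: with 1% of labels, a linear probe on frozen
    self-distilled features outperforms an identically-sized supervised
    backbone trained from scratch on the same labelled subset (median of the
    three training seeds)."""
    from celldistill.augment import eval_transform
    from celldistill.evaluation import single_label_macro_f1
    from celldistill.protocols import desk_train_config
    from celldistill.ssl import train_supervised

    train_images, train_labels, test_images, test_labels = corpus
    test_stack = np.stack([eval_transform(im, 32).data for im in test_images])
    train_stack = np.stack([eval_transform(im, 32).data for im in train_images])

    ssl_f1, sup_f1 = [], []
    for seed in (0, 1, 2):
        rng_s = np.random.default_rng(np.random.SeedSequence([seed, 21]))
        idx = stratified_subsample(train_labels, 0.01, rng_s)

        model = ssl_runs[seed]["model"]
        emb_train = model.embed(train_stack[idx]).data
        emb_test = model.embed(test_stack).data
        probe = train_probe(emb_train, train_labels[idx])
        ssl_f1.append(single_label_macro_f1(probe.predict(emb_test), test_labels))

        cfg = desk_train_config(seed)
        sup_model, clf = train_supervised(
            [train_images[i] for i in idx], train_labels[idx], cfg.backbone,
            n_classes=4, n_steps=250, batch_size=8, seed=seed)
        logits = clf(sup_model.embed(test_stack)).data
        sup_f1.append(single_label_macro_f1(logits.argmax(axis=1), test_labels))

    assert np.median(ssl_f1) > np.median(sup_f1)


def test_low_shot_fixed_seeds_reproduce_curves(rng):
    x = rng.normal(size=(60, 4))
    y = rng.integers(0, 2, size=60)
    xt = rng.normal(size=(20, 4))
    yt = rng.integers(0, 2, size=20)
    a = low_shot_protocol(x, y, xt, yt, fractions=(0.2, 1.0), seeds=(0, 1))
    b = low_shot_protocol(x, y, xt, yt, fractions=(0.2, 1.0), seeds=(0, 1))
    pd.testing.assert_frame_equal(a, b)
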