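"""Self-distillation losses against independent arithmetic oracles, EMA/center
updates, and single-step training contracts."""

import numpy as np
import pytest

import celldistill as cd
from celldistill import nn
from celldistill.errors import ConfigurationError
from celldistill.ssl import (ProjectionHead, TrainConfig, blockwise_mask,
                             dino_loss, ema_update, ibot_masked_loss,
                             koleo_loss, train, update_center)
from celldistill.vit import BackboneConfig


def np_softmax(x, axis=-1):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


# -- dino loss ---------------------------------------------------------------

def test_dino_loss_equals_entropy_when_distributions_match():
    # teacher and student produce the same distribution P for every view
    logits = np.array([[1.0, 0.3, -0.5]])
    tau = 0.1
    p = np_softmax(logits / tau)
    teacher = [logits / (0.04 / tau) * 0 + logits * (tau / 0.04)] * 2
    # choose teacher logits so softmax((t-0)/0.04) == softmax(s/0.1)
    teacher = [logits * (0.04 / tau) ** -1 * 0 + logits * (tau / 0.04) ** -1
               for _ in range(2)]
    teacher = [logits * (0.04 / tau)] * 2  # (t)/0.04 == s/0.1 => t = s*0.4
    student = [nn.Tensor(logits), nn.Tensor(logits)]
    loss = dino_loss(teacher, student, center=np.zeros(3), tau_t=0.04, tau_s=tau)
    entropy = -(p * np.log(p)).sum()
    assert loss.data == pytest.approx(entropy, abs=1e-10)


def test_dino_loss_one_hot_teacher_is_neg_log_q():
    teacher = [np.array([[50.0, 0.0, 0.0]]), np.array([[50.0, 0.0, 0.0]])]
    student_logits = np.array([[0.2, -0.1, 0.05]])
    student = [nn.Tensor(student_logits)] * 2
    loss = dino_loss(teacher, student, np.zeros(3), tau_t=0.04, tau_s=0.1)
    q = np_softmax(student_logits / 0.1)
    assert loss.data == pytest.approx(-np.log(q[0, 0]), abs=1e-9)


def test_dino_loss_matches_independent_oracle(rng):
    """K=3, 2 global views, 3 student views, hand-set logits: the pairwise
    cross-entropy mean recomputed with plain numpy."""
    k, b = 3, 2
    teacher = [rng.normal(size=(b, k)) for _ in range(2)]
    student_arr = [rng.normal(size=(b, k)) for _ in range(3)]
    center = rng.normal(size=k)
    tau_t, tau_s = 0.04, 0.1

    total, n = 0.0, 0
    for v, tl in enumerate(teacher):
        pt = np_softmax((tl - center) / tau_t)
        for u, sl in enumerate(student_arr):
            if u == v:
                continue
            log_q = np.log(np_softmax(sl / tau_s))
            total += -(pt * log_q).sum(axis=1).mean()
            n += 1
    expected = total / n

    loss = dino_loss(teacher, [nn.Tensor(s) for s in student_arr],
                     center, tau_t, tau_s)
    assert loss.data == pytest.approx(expected, abs=1e-6)


def test_dino_loss_requires_two_global_views():
    with pytest.raises(ConfigurationError):
        dino_loss([np.zeros((1, 3))], [nn.Tensor(np.zeros((1, 3)))] * 2,
                  np.zeros(3), 0.04, 0.1)


def test_dino_loss_gradient_flows_to_student_only(rng):
    teacher = [rng.normal(size=(2, 4)) for _ in range(2)]
    student = [nn.Tensor(rng.normal(size=(2, 4)), requires_grad=True)
               for _ in range(2)]
    loss = dino_loss(teacher, student, np.zeros(4), 0.04, 0.1)
    loss.backward()
    assert all(s.grad is not None for s in student)


# -- center and EMA ----------------------------------------------------------

def test_update_center_momentum_cases(rng):
    c = rng.normal(size=4)
    batch = rng.normal(size=(6, 4))
    assert np.allclose(update_center(c, batch, 1.0), c)
    assert np.allclose(update_center(c, batch, 0.0), batch.mean(axis=0))
    assert np.allclose(update_center(np.zeros(4), batch, 0.9),
                       0.1 * batch.mean(axis=0))


def test_ema_update_parameter_arithmetic(rng):
    t = nn.Linear(3, 2, np.random.default_rng(0))
    s = nn.Linear(3, 2, np.random.default_rng(1))
    t.weight.data[:] = 2.0
    s.weight.data[:] = 4.0
    ema_update(t, s, 0.5)
    assert np.allclose(t.weight.data, 3.0)
    ema_update(t, s, 1.0)
    assert np.allclose(t.weight.data, 3.0)  # m=1 leaves teacher unchanged
    ema_update(t, s, 0.0)
    assert np.allclose(t.weight.data, s.weight.data)  # m=0 copies student


# -- koleo -------------------------------------------------------------------

def test_koleo_antipodal_pair_closed_form():
    x = nn.Tensor(np.array([[1.0, 0.0], [-1.0, 0.0]]))
    assert koleo_loss(x).data == pytest.approx(-np.log(2.0), abs=1e-6)


def test_koleo_duplicates_guarded_finite():
    x = nn.Tensor(np.array([[1.0, 0.0], [1.0, 0.0]]))
    val = koleo_loss(x, eps=1e-8).data
    assert np.isfinite(val)
    assert val == pytest.approx(-np.log(1e-8), rel=0.01)


def test_koleo_scale_invariance(rng):
    x = rng.normal(size=(6, 5))
    a = koleo_loss(nn.Tensor(x)).data
    b = koleo_loss(nn.Tensor(7.3 * x)).data
    assert a == pytest.approx(b, abs=1e-9)


def test_koleo_decreases_as_points_spread():
    tight = nn.Tensor(np.array([[1.0, 0.01], [1.0, -0.01], [1.0, 0.02]]))
    spread = nn.Tensor(np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]]))
    assert koleo_loss(spread).data < koleo_loss(tight).data


def test_koleo_needs_two_points():
    with pytest.raises(ConfigurationError):
        koleo_loss(nn.Tensor(np.ones((1, 3))))


# -- iBOT --------------------------------------------------------------------

def test_ibot_empty_mask_is_zero(rng):
    s = nn.Tensor(rng.normal(size=(2, 4, 3)))
    t = rng.normal(size=(2, 4, 3))
    mask = np.zeros((2, 4), dtype=bool)
    assert ibot_masked_loss(s, t, mask, np.zeros(3), 0.04, 0.1).data == 0.0


def test_ibot_one_hot_teacher_single_masked_token(rng):
    s_logits = rng.normal(size=(1, 4, 3))
    t_logits = np.zeros((1, 4, 3))
    t_logits[0, 2] = [80.0, 0.0, 0.0]
    mask = np.zeros((1, 4), dtype=bool)
    mask[0, 2] = True
    loss = ibot_masked_loss(nn.Tensor(s_logits), t_logits, mask,
                            np.zeros(3), 0.04, 0.1)
    q = np_softmax(s_logits[0, 2] / 0.1)
    assert loss.data == pytest.approx(-np.log(q[0]), abs=1e-9)


def test_ibot_equal_distributions_give_mean_entropy(rng):
    logits = rng.normal(size=(1, 4, 3))
    mask = np.array([[True, True, False, False]])
    teacher = logits * (0.04 / 0.1)  # same distribution after sharpening
    loss = ibot_masked_loss(nn.Tensor(logits), teacher, mask,
                            np.zeros(3), 0.04, 0.1)
    p = np_softmax(logits[0, :2] / 0.1)
    entropy = -(p * np.log(p)).sum(axis=1).mean()
    assert loss.data == pytest.approx(entropy, abs=1e-9)


def test_blockwise_mask_ratio_and_shape(rng):
    mask = blockwise_mask((4, 4), batch=8, ratio=0.3, rng=rng)
    assert mask.shape == (8, 16)
    frac = mask.mean(axis=1)
    assert np.all(frac > 0) and np.all(frac <= 0.8)
    assert blockwise_mask((4, 4), 2, 0.0, rng).sum() == 0


# -- projection head ---------------------------------------------------------

def test_projection_head_output_size_and_norm(rng):
    head = ProjectionHead(16, hidden=32, bottleneck=8, n_prototypes=64)
    out = head(nn.Tensor(rng.normal(size=(5, 16))))
    assert out.shape == (5, 64)
    with pytest.raises(ConfigurationError):
        ProjectionHead(16, n_prototypes=1)


# -- the loop ---------------------------------------------------------------

def tiny_config(n_steps=1, **kw):
    crop, aug = cd.hpa_preset(global_size=32, local_size=16)
    crop.n_local = 2
    return TrainConfig(
        backbone=BackboneConfig(n_channels=4, patch_size=8, width=16, depth=1,
                                n_heads=2, image_size=32),
        crop=crop, aug=aug, head_hidden=32, head_bottleneck=8,
        n_prototypes=32, batch_size=4, n_steps=n_steps, warmup_steps=0,
        seed=0, **kw)


@pytest.fixture(scope="module")
def four_images():
    classes = ("nuclear", "cytoplasm", "membrane", "punctate")
    images = []
    for i in range(4):
        spec = cd.SceneSpec(height=32, width=32, n_cells=2,
                            localization_class=classes[i])
        images.append(cd.generate_scene(spec, i)[0])
    return images


def test_one_step_finite_loss_and_exact_ema(four_images):
    cfg = tiny_config(m_ema=0.9)
    from celldistill.vit import VisionTransformer

    init = VisionTransformer(cfg.backbone, seed=cfg.seed).state_dict()
    result = train(four_images, cfg)
    assert np.isfinite(result.trace["loss"]).all()
    student = result.student.state_dict()
    teacher = result.teacher.state_dict()
    for k in init:  # teacher = m*init + (1-m)*post-step student, recomputed
        assert np.allclose(teacher[k], 0.9 * init[k] + 0.1 * student[k],
                           atol=1e-12), k


def test_same_seed_reproduces_loss_trace(four_images):
    a = train(four_images, tiny_config(n_steps=3))
    b = train(four_images, tiny_config(n_steps=3))
    assert np.array_equal(a.trace["loss"].to_numpy(), b.trace["loss"].to_numpy())


def test_zero_weights_reduce_total_to_dino(four_images):
    res = train(four_images, tiny_config(lambda_ibot=0.0, lambda_koleo=0.0,
                                         mask_ratio=0.0))
    row = res.trace.iloc[0]
    assert row["loss"] == row["dino"]
    assert row["ibot"] == 0.0 and row["koleo"] == 0.0


def test_teacher_receives_no_gradient(four_images):
    res = train(four_images, tiny_config())
    for p in res.teacher.parameters() + res.head_teacher.parameters():
        assert p.grad is None


def test_teacher_distribution_is_not_collapsed(four_images):
    """Centering keeps the teacher target from degenerating onto a single
    prototype: the centered/sharpened distribution stays high-entropy and no
    prototype absorbs nearly all the mass."""
    res = train(four_images, tiny_config(n_steps=20))
    probes = []
    for i in range(12):
        spec = cd.SceneSpec(height=32, width=32, n_cells=2,
                            localization_class=("nuclear", "cytoplasm",
                                                "membrane", "punctate")[i % 4])
        probes.append(cd.generate_scene(spec, 50 + i)[0].data)
    with nn.no_grad():
        out = res.teacher.forward(np.stack(probes))
        logits = res.head_teacher(out.class_token).data
    p_t = np_softmax((logits - res.center) / 0.04)
    entropy = -(p_t * np.log(p_t + 1e-12)).sum(axis=1)
    assert np.all(p_t.max(axis=1) < 0.9)
    assert np.all(entropy > 0.5 * np.log(p_t.shape[1]))


def test_train_writes_loadable_checkpoint(four_images, tmp_path):
    from celldistill.vit import load_checkpoint

    path = tmp_path / "ckpt.zip"
    res = train(four_images, tiny_config(), checkpoint_path=path)
    model, extra, head_state = load_checkpoint(path)
    assert np.array_equal(model.state_dict()["cls_token"],
                          res.teacher.state_dict()["cls_token"])
    assert extra["train_config"]["n_steps"] == 1
    assert head_state  # teacher head saved alongside
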