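"""Self-distillation training: projection head, losses, EMA teacher, loop.

Two architecturally identical networks are trained: a student, updated by
gradient descent, and a teacher, maintained as an exponential moving average
of the student and receiving no gradients.  Both map each augmented view of
an image through the backbone and a projection head to a distribution over K
prototypes; the student is trained to match the teacher's (centered,
sharpened) distribution across views.  Centering (a momentum-updated running
mean subtracted from teacher logits) combined with a low teacher temperature
prevents collapse onto a single prototype.  Two auxiliary objectives are
used: a KoLeo regularizer that spreads class-token embeddings apart, and a
masked-patch (iBOT-style) cross-entropy at patch tokens the student saw
replaced by a learned mask token while the teacher saw the full view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .augment import AugConfig, CropConfig, ViewSet, multi_crop
from .errors import ConfigurationError
from .image import MultiChannelImage
from .vit import BackboneConfig, VisionTransformer, save_checkpoint


class ProjectionHead(nn.Module):
    """3-layer MLP to a bottleneck, L2-normalized, then K prototype logits."""

    def __init__(self, d_in: int, hidden: int = 2048, bottleneck: int = 256,
                 n_prototypes: int = 65536, seed: int = 0):
        super().__init__()
        if n_prototypes < 2:
            raise ConfigurationError("need at least 2 prototypes")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        self.n_prototypes = n_prototypes
        self.register("fc1", nn.Linear(d_in, hidden, rng))
        self.register("fc2", nn.Linear(hidden, hidden, rng))
        self.register("fc3", nn.Linear(hidden, bottleneck, rng))
        self.register("prototypes", nn.Linear(bottleneck, n_prototypes, rng, bias=False))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        z = self.fc3(self.fc2(self.fc1(x).gelu()).gelu())
        norm = ((z * z).sum(axis=-1, keepdims=True) + 1e-12).sqrt()
        return self.prototypes(z / norm)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _np_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def dino_loss(teacher_logits: list[np.ndarray], student_logits: list[nn.Tensor],
              center: np.ndarray, tau_t: float, tau_s: float) -> nn.Tensor:
    """Mean cross-entropy over ordered (teacher global view v, student view u != v).

    Teacher targets are centered and sharpened: softmax((logits - c) / tau_t),
    with no gradient; student distributions use softmax(logits / tau_s).
    Student views are indexed so that the first ``len(teacher_logits)``
    entries are the global views shared with the teacher.
    """
    if len(teacher_logits) < 2:
        raise ConfigurationError("need >= 2 teacher (global) views")
    total, n_pairs = None, 0
    for v, tl in enumerate(teacher_logits):
        p_t = _np_softmax((np.asarray(tl) - center) / tau_t)
        for u, sl in enumerate(student_logits):
            if u == v:
                continue
            log_q = nn.log_softmax(sl * (1.0 / tau_s))
            ce = -(nn.Tensor(p_t) * log_q).sum(axis=-1).mean()
            total = ce if total is None else total + ce
            n_pairs += 1
    return total * (1.0 / n_pairs)


def update_center(center: np.ndarray, teacher_logits_batch: np.ndarray,
                  m_center: float) -> np.ndarray:
    """c' = m*c + (1-m) * batch mean of teacher logits."""
    batch_mean = np.asarray(teacher_logits_batch).reshape(-1, center.shape[-1]).mean(axis=0)
    return m_center * center + (1.0 - m_center) * batch_mean


def ema_update(teacher: nn.Module, student: nn.Module, m_ema: float) -> None:
    """In place: every teacher parameter t' = m*t + (1-m)*s; no gradients flow."""
    t_params = teacher.named_parameters()
    s_params = student.named_parameters()
    for k, t in t_params.items():
        t.data = m_ema * t.data + (1.0 - m_ema) * s_params[k].data
        t.grad = None


def koleo_loss(embeddings: nn.Tensor, eps: float = 1e-8) -> nn.Tensor:
    """Negative mean log nearest-neighbour distance of L2-normalized embeddings."""
    n = embeddings.shape[0]
    if n < 2:
        raise ConfigurationError("KoLeo needs a batch of >= 2 embeddings")
    norm = ((embeddings * embeddings).sum(axis=-1, keepdims=True) + 1e-12).sqrt()
    x = embeddings / norm
    sims = x.data @ x.data.T
    np.fill_diagonal(sims, -np.inf)
    nearest = sims.argmax(axis=1)  # max cosine = min distance on the sphere
    diff = x - x[nearest]
    dist = ((diff * diff).sum(axis=-1) + 1e-20).sqrt()
    return -(dist + eps).log().mean()


def ibot_masked_loss(student_patch_logits: nn.Tensor, teacher_patch_logits: np.ndarray,
                     mask: np.ndarray, center: np.ndarray,
                     tau_t: float, tau_s: float) -> nn.Tensor:
    """Centered/sharpened cross-entropy at masked patch positions only."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return nn.Tensor(0.0)
    idx = np.nonzero(mask)
    p_t = _np_softmax((np.asarray(teacher_patch_logits)[idx] - center) / tau_t)
    log_q = nn.log_softmax(student_patch_logits[idx] * (1.0 / tau_s))
    return -(nn.Tensor(p_t) * log_q).sum(axis=-1).mean()


def blockwise_mask(grid: tuple[int, int], batch: int, ratio: float,
                   rng: np.random.Generator) -> np.ndarray:
    """One random rectangular block of ~ratio of the patch grid per image."""
    gh, gw = grid
    n = gh * gw
    mask = np.zeros((batch, n), dtype=bool)
    if ratio <= 0:
        return mask
    target = max(1, int(round(ratio * n)))
    for b in range(batch):
        bh = int(rng.integers(1, gh + 1))
        bw = max(1, min(gw, int(round(target / bh))))
        y0 = int(rng.integers(0, gh - bh + 1))
        x0 = int(rng.integers(0, gw - bw + 1))
        m = np.zeros((gh, gw), dtype=bool)
        m[y0:y0 + bh, x0:x0 + bw] = True
        mask[b] = m.ravel()
    return mask


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    crop: CropConfig = field(default_factory=CropConfig)
    aug: AugConfig = field(default_factory=lambda: AugConfig(protein_channel_index=3))
    head_hidden: int = 256
    head_bottleneck: int = 64
    n_prototypes: int = 1024          # reference configuration uses 65,536
    tau_s: float = 0.1
    tau_t_start: float = 0.04
    tau_t_end: float = 0.07
    m_center: float = 0.9
    m_ema: float = 0.996
    lambda_koleo: float = 0.1
    lambda_ibot: float = 1.0
    mask_ratio: float = 0.3
    lr: float = 2e-3
    warmup_steps: int = 30
    weight_decay: float = 0.04
    batch_size: int = 16
    n_steps: int = 300
    seed: int = 0
    grad_clip: float = 3.0


@dataclass
class TrainResult:
    student: VisionTransformer
    teacher: VisionTransformer
    head_student: ProjectionHead
    head_teacher: ProjectionHead
    trace: pd.DataFrame
    center: np.ndarray | None = None
    center_patch: np.ndarray | None = None


def _clip_gradients(params: list[nn.Tensor], max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _stack_views(viewsets: list[ViewSet]) -> tuple[np.ndarray, np.ndarray | None, int, int]:
    """Stack global and local views across the batch: view-major ordering."""
    n_global = len(viewsets[0].global_views)
    n_local = len(viewsets[0].local_views)
    g = np.stack([vs.global_views[v].data for v in range(n_global) for vs in viewsets])
    l = None
    if n_local:
        l = np.stack([vs.local_views[v].data for v in range(n_local) for vs in viewsets])
    return g, l, n_global, n_local


def train(images: list[MultiChannelImage], cfg: TrainConfig,
          checkpoint_path=None, log_every: int = 10) -> TrainResult:
    """Run the self-distillation loop on an in-memory image collection.

    Per step: sample a batch, build multi-crop views, run the student on all
    views and the teacher on global views, combine the view-matching loss
    with the masked-patch and KoLeo terms, step the student, then update the
    teacher (EMA) and the centers.  Deterministic for a fixed config seed in
    single-process mode.
    """
    if cfg.n_steps < 1:
        raise ConfigurationError("need at least one training step")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    student = VisionTransformer(cfg.backbone, seed=cfg.seed)
    teacher = VisionTransformer(cfg.backbone, seed=cfg.seed)
    teacher.load_state_dict(student.state_dict())
    d = cfg.backbone.width
    head_s = ProjectionHead(d, cfg.head_hidden, cfg.head_bottleneck,
                            cfg.n_prototypes, seed=cfg.seed)
    head_t = ProjectionHead(d, cfg.head_hidden, cfg.head_bottleneck,
                            cfg.n_prototypes, seed=cfg.seed)
    head_t.load_state_dict(head_s.state_dict())

    params = student.parameters() + head_s.parameters()
    opt = nn.AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    lr_sched = nn.cosine_schedule(cfg.lr, cfg.lr * 0.01, cfg.n_steps, cfg.warmup_steps)
    tau_t_sched = np.linspace(cfg.tau_t_start, cfg.tau_t_end,
                              min(cfg.n_steps, 100))

    center = np.zeros(cfg.n_prototypes)
    center_patch = np.zeros(cfg.n_prototypes)
    trace_rows = []

    for step in range(cfg.n_steps):
        batch_idx = rng.integers(0, len(images), size=cfg.batch_size)
        viewsets = [multi_crop(images[i], cfg.crop, cfg.aug, rng) for i in batch_idx]
        g_views, l_views, n_global, n_local = _stack_views(viewsets)
        b = cfg.batch_size
        tau_t = float(tau_t_sched[min(step, len(tau_t_sched) - 1)])

        # teacher: global views, unmasked, no graph
        with nn.no_grad():
            t_out = teacher.forward(g_views)
            t_cls_logits = head_t(t_out.class_token).data.reshape(n_global, b, -1)
            t_patch_logits = head_t(t_out.patch_tokens[:b]).data  # view 0

        # student: view 0 masked for the masked-patch objective
        grid = (cfg.backbone.image_size // cfg.backbone.patch_size,) * 2
        n_tokens = grid[0] * grid[1]
        mask = np.zeros((n_global * b, n_tokens), dtype=bool)
        mask[:b] = blockwise_mask(grid, b, cfg.mask_ratio, rng)
        s_out = student.forward(g_views, mask=mask)
        s_cls_logits_g = head_s(s_out.class_token)
        student_logits = [s_cls_logits_g[v * b:(v + 1) * b] for v in range(n_global)]
        if n_local:
            s_out_l = student.forward(l_views)
            s_cls_logits_l = head_s(s_out_l.class_token)
            student_logits += [s_cls_logits_l[v * b:(v + 1) * b] for v in range(n_local)]

        loss_dino = dino_loss(list(t_cls_logits), student_logits, center,
                              tau_t, cfg.tau_s)
        loss_ibot = nn.Tensor(0.0)
        if cfg.lambda_ibot > 0 and cfg.mask_ratio > 0:
            s_patch_logits = head_s(s_out.patch_tokens[:b])
            loss_ibot = ibot_masked_loss(s_patch_logits, t_patch_logits, mask[:b],
                                         center_patch, tau_t, cfg.tau_s)
        loss_koleo = nn.Tensor(0.0)
        if cfg.lambda_koleo > 0:
            loss_koleo = koleo_loss(s_out.class_token)

        total = loss_dino + cfg.lambda_ibot * loss_ibot + cfg.lambda_koleo * loss_koleo
        if not np.isfinite(total.data):
            raise RuntimeError(
                f"non-finite loss at step {step}: dino={loss_dino.data}, "
                f"ibot={loss_ibot.data}, koleo={loss_koleo.data}")

        opt.zero_grad()
        total.backward()
        _clip_gradients(params, cfg.grad_clip)
        opt.lr = float(lr_sched[step])
        opt.step()

        ema_update(teacher, student, cfg.m_ema)
        ema_update(head_t, head_s, cfg.m_ema)
        center = update_center(center, t_cls_logits, cfg.m_center)
        center_patch = update_center(center_patch, t_patch_logits, cfg.m_center)

        trace_rows.append({"step": step, "loss": float(total.data),
                           "dino": float(loss_dino.data),
                           "ibot": float(loss_ibot.data),
                           "koleo": float(loss_koleo.data),
                           "lr": float(lr_sched[step]), "tau_t": tau_t,
                           "m_ema": cfg.m_ema})

    trace = pd.DataFrame(trace_rows)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, teacher,
                        extra={"train_config": {"n_steps": cfg.n_steps,
                                                "seed": cfg.seed}},
                        head_state=head_t.state_dict())
    return TrainResult(student, teacher, head_s, head_t, trace, center, center_patch)


# ---------------------------------------------------------------------------
# supervised reference trainer (used by the low-shot comparisons)
# ---------------------------------------------------------------------------

def train_supervised(images: list[MultiChannelImage], labels: np.ndarray,
                     backbone_cfg: BackboneConfig, n_classes: int,
                     n_steps: int = 300, batch_size: int = 16, lr: float = 1e-3,
                     seed: int = 0, crop_size: int | None = None) -> tuple[VisionTransformer, nn.Module]:
    """Train backbone + linear classifier end-to-end with softmax cross-entropy.

    This is the from-scratch supervised baseline protocol: same architecture
    as the self-supervised backbone, all parameters updated from labels.
    """
    from .augment import eval_transform

    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    model = VisionTransformer(backbone_cfg, seed=seed)
    head_rng = np.random.default_rng(np.random.SeedSequence([seed, 14]))
    clf = nn.Linear(2 * backbone_cfg.width, n_classes, head_rng)
    params = model.parameters() + clf.parameters()
    opt = nn.AdamW(params, lr=lr, weight_decay=0.01)
    size = crop_size or backbone_cfg.image_size
    data = np.stack([eval_transform(im, size).data for im in images])
    labels = np.asarray(labels)

    for step in range(n_steps):
        idx = rng.integers(0, len(images), size=min(batch_size, len(images)))
        logits = clf(model.embed(data[idx]))
        log_q = nn.log_softmax(logits)
        onehot = np.eye(n_classes)[labels[idx]]
        loss = -(nn.Tensor(onehot) * log_q).sum(axis=-1).mean()
        opt.zero_grad()
        loss.backward()
        _clip_gradients(params, 3.0)
        opt.step()
    return model, clf
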