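"""Optimisers and learning-rate schedules for the self-distillation loop."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.04):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_schedule(base: float, final: float, n_steps: int, warmup: int = 0) -> np.ndarray:
    """Per-step values: linear warmup from 0 to ``base`` then cosine decay to ``final``."""
    n_steps = max(n_steps, 1)
    out = np.empty(n_steps)
    warmup = min(warmup, n_steps)
    if warmup > 0:
        out[:warmup] = base * np.arange(1, warmup + 1) / warmup
    rest = n_steps - warmup
    if rest > 0:
        t = np.arange(rest) / max(rest - 1, 1)
        out[warmup:] = final + 0.5 * (base - final) * (1 + np.cos(np.pi * t))
    return out
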