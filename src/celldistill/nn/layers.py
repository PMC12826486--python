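"""Neural-network building blocks on top of the autodiff core.

Initialisation follows the truncated-normal (sigma = 0.02) convention for
weights and zeros for biases.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, softmax


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated at two standard deviations, by resampling."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2.0 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2.0 * std
    return out


class Module:
    """Minimal module container with named parameters and state-dict I/O."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}

    def register(self, name: str, value) -> Tensor | "Module":
        if isinstance(value, Module):
            self._modules[name] = value
        else:
            t = value if isinstance(value, Tensor) else Tensor(value, requires_grad=True)
            t.requires_grad = True
            self._params[name] = t
        setattr(self, name, value if isinstance(value, Module) else self._params[name])
        return getattr(self, name)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, v in params.items():
            v.data = np.array(state[k], dtype=np.float64)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.register("weight", trunc_normal(rng, (d_in, d_out)))
        self.has_bias = bias
        if bias:
            self.register("bias", np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.has_bias:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.register("gamma", np.ones(dim))
        self.register("beta", np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim, self.n_heads, self.head_dim = dim, n_heads, dim // n_heads
        self.register("qkv", Linear(dim, 3 * dim, rng))
        self.register("proj", Linear(dim, dim, rng))

    def forward(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(b, n, 3, h, hd).transpose((2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]  # (b, h, n, hd)
        att = softmax((q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(hd)), axis=-1)
        y = (att @ v).transpose((0, 2, 1, 3)).reshape(b, n, d)
        return self.proj(y)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.register("fc1", Linear(dim, hidden, rng))
        self.register("fc2", Linear(hidden, dim, rng))

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class TransformerBlock(Module):
    """Pre-norm transformer block: x + MHSA(LN(x)), then x + FFN(LN(x))."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, mlp_ratio: float = 4.0):
        super().__init__()
        self.register("norm1", LayerNorm(dim))
        self.register("attn", MultiHeadSelfAttention(dim, n_heads, rng))
        self.register("norm2", LayerNorm(dim))
        self.register("mlp", FeedForward(dim, int(dim * mlp_ratio), rng))

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(x))
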