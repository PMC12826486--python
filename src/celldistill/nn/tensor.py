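"""Compact reverse-mode automatic differentiation on numpy arrays.

The training loop in this package needs gradients for a small vision
transformer, its projection head, and a handful of losses.  This module
provides exactly that: a :class:`Tensor` wrapping a float64 ndarray, a tape
of primitive operations with hand-written vector-Jacobian products, and a
``backward`` that walks the tape in reverse topological order.  Broadcasting
follows numpy semantics; gradients of broadcast operands are summed back to
the operand's shape.

Gradient correctness for every primitive is established by central-difference
checks in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Iterable

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context in which no computation graph is recorded (e.g. teacher forward)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(p for p in parents if p.requires_grad)
        return out

    def _set_bw(self, bw) -> None:
        if self.requires_grad:
            self._backward = bw

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._set_bw(bw)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._set_bw(bw)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other.powi(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def powi(self, exponent: float) -> "Tensor":
        """Elementwise power with a constant exponent."""
        out = self._make(self.data ** exponent, (self,), None)

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        out._set_bw(bw)
        return out

    def __pow__(self, exponent):
        return self.powi(float(exponent))

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def bw(g):
            # 1-D operands follow numpy's vector promotion rules and need
            # explicit contractions; batched matrices use the generic form.
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.expand_dims(g, -1) * other.data
                elif self.data.ndim == 1:
                    k, m = other.data.shape[-2:]
                    ga = np.einsum("pkm,pm->k", other.data.reshape(-1, k, m),
                                   g.reshape(-1, m))
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.expand_dims(self.data, -1) * np.expand_dims(g, -2)
                elif other.data.ndim == 1:
                    d = self.data.shape[-1]
                    gb = g.reshape(-1) @ self.data.reshape(-1, d)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._set_bw(bw)
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = self._make(val, (self,), None)
        out._set_bw(lambda g: self._accum(g * val))
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.data), (self,), None)
        out._set_bw(lambda g: self._accum(g / self.data))
        return out

    def tanh(self) -> "Tensor":
        val = np.tanh(self.data)
        out = self._make(val, (self,), None)
        out._set_bw(lambda g: self._accum(g * (1.0 - val * val)))
        return out

    def sqrt(self) -> "Tensor":
        val = np.sqrt(self.data)
        out = self._make(val, (self,), None)
        out._set_bw(lambda g: self._accum(g * 0.5 / val))
        return out

    def gelu(self) -> "Tensor":
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = self._make(x * cdf, (self,), None)

        def bw(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            self._accum(g * (cdf + x * pdf))

        out._set_bw(bw)
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._set_bw(bw)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation -------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,), None)
        out._set_bw(lambda g: self._accum(g.reshape(self.data.shape)))
        return out

    def transpose(self, axes: tuple[int, ...]) -> "Tensor":
        out = self._make(self.data.transpose(axes), (self,), None)
        inv = np.argsort(axes)
        out._set_bw(lambda g: self._accum(g.transpose(inv)))
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = self._make(np.swapaxes(self.data, a, b), (self,), None)
        out._set_bw(lambda g: self._accum(np.swapaxes(g, a, b)))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = self._make(self.data[idx], (self,), None)

        def bw(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accum(buf)

        out._set_bw(bw)
        return out

    @staticmethod
    def cat(tensors: Iterable["Tensor"], axis: int = 0) -> "Tensor":
        tensors = list(tensors)
        data = np.concatenate([t.data for t in tensors], axis=axis)
        out = Tensor(data)
        if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
            out.requires_grad = True
            out._prev = tuple(t for t in tensors if t.requires_grad)
            sizes = [t.data.shape[axis] for t in tensors]
            offsets = np.cumsum([0] + sizes)

            def bw(g):
                for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                    if t.requires_grad:
                        sl = [slice(None)] * g.ndim
                        sl[axis] = slice(lo, hi)
                        t._accum(g[tuple(sl)])

            out._set_bw(bw)
        return out

    # -- backward ----------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max-shift is a constant w.r.t. the graph."""
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()
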