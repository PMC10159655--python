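"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the per-node classifier needs: embedding
lookup, broadcasting add/multiply, batched matrix multiplication, reshape /
transpose / concatenation, ReLU, softmax, masked mean-pooling and a fused
softmax-cross-entropy loss.  Gradients are accumulated by a topological
backward sweep; correctness is checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode); saves time and memory."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data: Array | float, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[Array], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: Array) -> None:
        # first contribution takes ownership; later ones allocate a fresh sum
        # (gradients are treated as read-only, so sharing is safe)
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad: Array | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def _build(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                _build(p)
            topo.append(t)

        _build(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers ---------------------------------------------------------
    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _make(data: Array, parents: Sequence[Tensor],
          backward: Callable[[Array], None] | None) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED:
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
    return out


# ---------------------------------------------------------------------------
# Elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))
    return _make(a.data + b.data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))
    return _make(a.data * b.data, (a, b), bwd)


def scale(a: Tensor, s: float) -> Tensor:
    def bwd(g: Array) -> None:
        a._accumulate(g * s)
    return _make(a.data * s, (a,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matmul with numpy broadcasting of leading dimensions."""
    def bwd(g: Array) -> None:
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.shape))
    return _make(np.matmul(a.data, b.data), (a, b), bwd)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    def bwd(g: Array) -> None:
        a._accumulate(g * mask)
    return _make(a.data * mask, (a,), bwd)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    def bwd(g: Array) -> None:
        a._accumulate(g.reshape(a.shape))
    return _make(a.data.reshape(shape), (a,), bwd)


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    inv = tuple(np.argsort(axes))
    def bwd(g: Array) -> None:
        a._accumulate(g.transpose(inv))
    return _make(a.data.transpose(axes), (a,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bwd(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])
    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# Neural-network ops
# ---------------------------------------------------------------------------

def embedding(table: Tensor, indices: Array) -> Tensor:
    """Row lookup: out[..., :] = table[indices[...], :]."""
    idx = np.asarray(indices)
    def bwd(g: Array) -> None:
        grad = np.zeros_like(table.data)
        np.add.at(grad, idx.ravel(), g.reshape(-1, table.data.shape[1]))
        table._accumulate(grad)
    return _make(table.data[idx], (table,), bwd)


def softmax(a: Tensor, mask_add: Array | None = None) -> Tensor:
    """Softmax over the last axis, with an optional additive (no-grad) mask.

    ``mask_add`` is broadcast onto ``a`` before normalization; use large
    (finite) negative values to exclude padded keys.  A fully masked row
    degenerates to a uniform distribution over its masked keys; callers that
    mask whole sequences must also exclude them downstream (the pooled
    feature mask does exactly that).
    """
    z = a.data if mask_add is None else a.data + mask_add.astype(a.data.dtype)
    zmax = np.max(z, axis=-1, keepdims=True)
    e = np.exp(z - zmax)
    y = e / e.sum(axis=-1, keepdims=True)
    def bwd(g: Array) -> None:
        dot = np.sum(g * y, axis=-1, keepdims=True)
        a._accumulate(y * (g - dot))
    return _make(y, (a,), bwd)


def dropout(a: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (deterministic mode)."""
    if rng is None or rate <= 0:
        return a
    keep = ((rng.random(a.shape, dtype=np.float32) >= rate)
            .astype(a.data.dtype) / (1.0 - rate))
    def bwd(g: Array) -> None:
        a._accumulate(g * keep)
    return _make(a.data * keep, (a,), bwd)


def masked_mean_pool(a: Tensor, mask: Array) -> Tensor:
    """Mean over axis -2 restricted to positions where ``mask`` is true.

    ``a``: (..., L, E); ``mask``: (..., L).  Sequences with no valid
    position pool to the zero vector.
    """
    m = np.asarray(mask).astype(a.data.dtype)[..., None]    # (..., L, 1)
    counts = m.sum(axis=-2, keepdims=True)                  # (..., 1, 1)
    safe = np.maximum(counts, 1.0)
    out = (a.data * m).sum(axis=-2) / safe[..., 0, :]
    def bwd(g: Array) -> None:
        a._accumulate(g[..., None, :] * m / safe)
    return _make(out, (a,), bwd)


def cross_entropy(logits: Tensor, labels: Array) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class ids (B,)."""
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z - zmax).sum(axis=-1, keepdims=True)) + zmax
    logp = z - logsumexp
    n = z.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    def bwd(g: Array) -> None:
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accumulate((g * p / n).astype(logits.data.dtype))
    return _make(np.asarray(loss), (logits,), bwd)


# ---------------------------------------------------------------------------
# Parameters and optimizer
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data: Array):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: Iterable[Parameter], lr: float = 0.005,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
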