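"""Tape-based reverse-mode automatic differentiation over NumPy arrays.

The model in this package is trained by gradient descent, so every building
block (message passing, attention, gating, readout) is expressed in terms of
the small set of differentiable primitives defined here: broadcast-aware
arithmetic, matrix products, row gathering, segment reductions, and a few
pointwise nonlinearities.  All data is float64; gradients are accumulated on
``Tensor.grad`` by :meth:`Tensor.backward` via a topological sweep of the tape.

Segment operations (``segment_sum`` / ``segment_mean`` / ``segment_max``) are
the graph-batching workhorses: molecules of different sizes are packed into one
flat array of atom rows with an integer segment id per row, in the style used
by graph neural-network libraries.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "concat",
    "segment_sum",
    "segment_mean",
    "segment_max",
    "numeric_gradient",
    "no_grad",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Skip tape construction inside the block (inference-only passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _scatter_add(out: np.ndarray, ids: np.ndarray, values: np.ndarray) -> None:
    """out[ids] += values via flat bincount (much faster than np.add.at)."""
    n = out.shape[0]
    if values.ndim == 1:
        out += np.bincount(ids, weights=values, minlength=n)
        return
    d = values.shape[1]
    flat = np.bincount(
        (ids[:, None] * d + np.arange(d)[None, :]).ravel(),
        weights=values.ravel(), minlength=n * d,
    )
    out += flat.reshape(n, d)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- tape construction -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; training graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(grad, self.data.shape),
                                 dtype=np.float64)
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return _as_tensor(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        def backward(g):
            self._accumulate(g.T)

        return Tensor._make(self.data.T, (self,), backward)

    def __getitem__(self, key) -> "Tensor":
        fancy = isinstance(key, np.ndarray) and key.dtype.kind in "iu"

        def backward(g):
            if not self.requires_grad:
                return
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            if fancy:
                _scatter_add(self.grad, key, g)
            else:
                self.grad[key] += g

        return Tensor._make(self.data[key], (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise ---------------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def square(self) -> "Tensor":
        return self * self

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, slope)

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = ((self.data >= lo) & (self.data <= hi)).astype(np.float64)

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    """A tensor that never takes gradient (input data, masks, noise draws)."""
    return Tensor(x, requires_grad=False)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def segment_sum(x: Tensor, ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `x` into `num_segments` buckets given per-row integer ids."""
    ids = np.asarray(ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    _scatter_add(out_data, ids, x.data)

    def backward(g):
        x._accumulate(g[ids])

    return Tensor._make(out_data, (x,), backward)


def segment_mean(x: Tensor, ids: np.ndarray, num_segments: int) -> Tensor:
    ids = np.asarray(ids, dtype=np.intp)
    counts = np.bincount(ids, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    shape = (num_segments,) + (1,) * (x.data.ndim - 1)
    return segment_sum(x, ids, num_segments) * constant(1.0 / counts.reshape(shape))


def segment_max(x: np.ndarray, ids: np.ndarray, num_segments: int) -> np.ndarray:
    """Per-segment max of raw data (used only as a constant shift in softmax)."""
    ids = np.asarray(ids, dtype=np.intp)
    out = np.full((num_segments,) + x.shape[1:], -np.inf)
    np.maximum.at(out, ids, x)
    return out


def numeric_gradient(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar-valued `fn`; test utility."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (fn(xp) - fn(xm)) / (2 * eps)
        it.iternext()
    return g
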