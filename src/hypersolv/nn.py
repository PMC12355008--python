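"""Neural building blocks on top of :mod:`hypersolv.autodiff`.

Layers hold their parameters as :class:`~hypersolv.autodiff.Tensor` objects
with ``requires_grad=True``; ``parameters()`` walks them for the optimizer.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .autodiff import Tensor, constant, concat, segment_max, segment_sum

__all__ = ["Linear", "LSTMCell", "Adam", "dropout", "segment_softmax", "cosine_lr"]


class Linear:
    """Affine map ``x @ W + b`` with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        self.n_in, self.n_out = n_in, n_out
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            a = math.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-a, a, size=(n_in, n_out))
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.n_in:
            raise ValueError(
                f"linear map expects input width {self.n_in}, got {x.shape[-1]}"
            )
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def parameters(self) -> list[Tensor]:
        return [self.W] + ([self.b] if self.b is not None else [])


class LSTMCell:
    """Single LSTM cell (gate order i, f, g, o; forget bias +1)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.wx = Linear(n_in, 4 * n_hidden, rng, bias=True)
        self.wh = Linear(n_hidden, 4 * n_hidden, rng, bias=False)
        b = self.wx.b.data
        b[n_hidden:2 * n_hidden] = 1.0

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        nh = self.n_hidden
        z = self.wx(x) + self.wh(h)
        i = z[:, 0 * nh:1 * nh].sigmoid()
        f = z[:, 1 * nh:2 * nh].sigmoid()
        g = z[:, 2 * nh:3 * nh].tanh()
        o = z[:, 3 * nh:4 * nh].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def parameters(self) -> list[Tensor]:
        return self.wx.parameters() + self.wh.parameters()


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * constant(mask)


def segment_softmax(scores: Tensor, ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a score vector normalized within each segment."""
    ids = np.asarray(ids, dtype=np.intp)
    shift = segment_max(scores.data, ids, num_segments)[ids]
    e = (scores - constant(shift)).exp()
    denom = segment_sum(e, ids, num_segments)
    return e / denom[ids]


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cosine_lr(epoch: int, max_epochs: int, lr_init: float, lr_min: float = 1e-6) -> float:
    """Cosine annealing from ``lr_init`` down to ``lr_min`` over ``max_epochs``."""
    if max_epochs <= 1:
        return lr_init
    frac = min(epoch, max_epochs - 1) / (max_epochs - 1)
    return lr_min + 0.5 * (lr_init - lr_min) * (1.0 + math.cos(math.pi * frac))
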