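"""Graph-information-bottleneck gating of hypernode embeddings.

Each hypernode gets a learned transmission probability p_i (sigmoid of a
linear map of its embedding).  During training a concrete (Gumbel-sigmoid)
relaxation draws a soft gate lambda_i in (0, 1) from p_i, and the hypernode
embedding is mixed with Gaussian noise whose per-dimension moments are those
of the molecule's own hypernode embeddings:

    z_i = lambda_i * H_i + (1 - lambda_i) * eps_i,
    eps_i ~ Normal(mu_H, diag(sigma_H^2)).

The mutual information between the original and the gated hypergraph is
penalized through the analytic upper bound

    -1/2 log A + A / (2m) + ||B||^2 / (2m),
    A = sum_j (1 - lambda_j)^2,
    B = sum_j lambda_j (H_j - mu_H) / sigma_H,

per molecule with m hypernodes; the composite training objective is the
squared prediction error plus beta times the two molecules' bounds.

At inference the gates are evaluated at their means (lambda_i = p_i, noise at
its mean mu_H), which makes predictions and explanations deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, constant, segment_mean, segment_sum
from .errors import ConfigError
from .nn import Linear

__all__ = [
    "GibConfig",
    "GateState",
    "gate_probabilities",
    "sample_relaxed_gates",
    "molecule_moments",
    "inject_noise",
    "mi_upper_bound",
    "total_loss",
]

GATE_CLAMP = 1e-6
SIGMA_FLOOR = 1e-6


@dataclass
class GibConfig:
    beta: float = 1e-4
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.beta < 0:
            raise ConfigError("beta must be non-negative")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")


@dataclass
class GateState:
    """Gates, noise moments and gated embeddings for one side of a batch."""

    p: Tensor       # (C, 1) transmission probabilities
    lam: Tensor     # (C, 1) relaxed gates (== p at inference)
    z: Tensor       # (C, d) gated hypernode embeddings
    mu: Tensor      # (G, d) per-molecule embedding means
    sigma: Tensor   # (G, d) per-molecule embedding standard deviations
    graph_ids: np.ndarray  # (C,) molecule id per hypernode
    m: np.ndarray   # (G,) hypernode counts per molecule


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(x)


def gate_probabilities(hyper_embeddings: Tensor, fc: Linear) -> Tensor:
    """p_i = sigmoid(FC(H_i)), one scalar per hypernode, shape (C, 1)."""
    return fc(_as_tensor(hyper_embeddings)).sigmoid()


def sample_relaxed_gates(p: Tensor, temperature: float,
                         rng: np.random.Generator) -> Tensor:
    """Concrete relaxation: sigmoid((logit p + logit u) / t), u ~ Uniform(0,1)."""
    p = _as_tensor(p).clip(GATE_CLAMP, 1.0 - GATE_CLAMP)
    u = np.clip(rng.random(p.shape), GATE_CLAMP, 1.0 - GATE_CLAMP)
    noise = constant(np.log(u / (1.0 - u)))
    logit_p = (p / (1.0 - p)).log()
    return ((logit_p + noise) * (1.0 / temperature)).sigmoid()


def molecule_moments(hyper_embeddings: Tensor, graph_ids: np.ndarray,
                     n_graphs: int) -> tuple[Tensor, Tensor]:
    """Per-molecule, per-dimension mean and (floored) standard deviation."""
    h = _as_tensor(hyper_embeddings)
    mu = segment_mean(h, graph_ids, n_graphs)
    var = segment_mean(h.square(), graph_ids, n_graphs) - mu.square()
    sigma = var.clip(SIGMA_FLOOR**2, np.inf).sqrt()
    return mu, sigma


def inject_noise(hyper_embeddings: Tensor, lam: Tensor, mu: Tensor, sigma: Tensor,
                 graph_ids: np.ndarray, rng: np.random.Generator | None = None) -> Tensor:
    """z_i = lam_i * H_i + (1 - lam_i) * eps_i.

    With ``rng=None`` the noise is replaced by its mean (deterministic
    inference path).
    """
    h = _as_tensor(hyper_embeddings)
    lam = _as_tensor(lam)
    eps = mu[graph_ids]
    if rng is not None:
        eps = eps + sigma[graph_ids] * constant(rng.standard_normal(h.shape))
    return lam * h + (1.0 - lam) * eps


def mi_upper_bound(lam: Tensor, hyper_embeddings: Tensor, mu: Tensor, sigma: Tensor,
                   graph_ids: np.ndarray | None = None,
                   n_graphs: int = 1) -> Tensor:
    """Analytic per-molecule upper bound on I(H; H_gated), shape (G,).

    Natural logarithm; lambda is clamped below 1 so A stays positive.
    """
    h = _as_tensor(hyper_embeddings)
    lam = _as_tensor(lam).clip(0.0, 1.0 - GATE_CLAMP)
    if lam.ndim == 1:
        lam = lam.reshape(-1, 1)
    if graph_ids is None:
        graph_ids = np.zeros(h.shape[0], dtype=np.intp)
    m = np.bincount(graph_ids, minlength=n_graphs).astype(np.float64)
    a = segment_sum((1.0 - lam).square(), graph_ids, n_graphs)        # (G, 1)
    b = segment_sum(lam * ((h - mu[graph_ids]) / sigma[graph_ids]),
                    graph_ids, n_graphs)                              # (G, d)
    b_sq = b.square().sum(axis=1, keepdims=True)                      # (G, 1)
    inv_2m = constant((1.0 / (2.0 * np.maximum(m, 1.0))).reshape(-1, 1))
    bound = a.log() * (-0.5) + a * inv_2m + b_sq * inv_2m
    return bound.reshape(-1)


def total_loss(prediction: Tensor, label, bound1: Tensor, bound2: Tensor,
               beta: float) -> Tensor:
    """L = mean squared error + beta * (mean bound1 + mean bound2)."""
    prediction = _as_tensor(prediction)
    err = (prediction - _as_tensor(label)).square().mean()
    if beta == 0.0:
        return err
    return err + beta * (_as_tensor(bound1).mean() + _as_tensor(bound2).mean())
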