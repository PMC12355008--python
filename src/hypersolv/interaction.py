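"""Alternating intra-/intermolecular message passing over hypergraph pairs.

Each of the L rounds performs, in order: an intramolecular edge/node update on
the solute, the same on the solvent, mean-pooling of atom embeddings into
hypernode embeddings, solute-solvent co-attention between hypernodes, and a
gamma-mixed broadcast of the attended hypernode messages back onto the member
atoms.

The intramolecular update is residual throughout: edges gain a LeakyReLU of
linear maps of the incident atoms, the edge itself, and the global embedding;
a sigmoid edge gate, normalized over each receiving atom's neighborhood (with
a fixed ``eps`` in the denominator), modulates the neighbor sum of the node
update.  The attention scores are raw dot products of hypernode embeddings
(optionally 1/sqrt(d)-scaled); the solute side is normalized per row, the
solvent side renormalizes the same score table per column so that both message
sets are convex combinations computed from pre-update embeddings.

Batches pack the atoms of many molecules into flat arrays with integer graph /
hypernode segment ids, so one pass handles any mixture of molecule sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat, constant, segment_mean, segment_sum
from .errors import ConfigError, InputError
from .molgraph import FeatureProjector, MolecularGraph
from .nn import Linear
from .vocab import Hypergraph

__all__ = [
    "NetConfig",
    "PackedMolecules",
    "PairState",
    "InteractionParams",
    "pack_molecules",
    "intra_step",
    "pool_hypernodes",
    "cross_attention",
    "broadcast_update",
    "run_rounds",
]


@dataclass
class NetConfig:
    """Message-passing hyperparameters.

    ``gamma`` is the intermolecular update rate: 0 disables cross-molecular
    exchange entirely, 1 overwrites every atom with its hypernode message.
    """

    L: int = 4
    d: int = 300
    gamma: float = 0.2
    leaky_slope: float = 0.01
    eps: float = 1e-8
    prior_bias: float = 0.0
    pooling: str = "mean"  # mean | sum | max
    scale_scores: bool = False

    def __post_init__(self):
        if not (0.0 <= self.gamma <= 1.0):
            raise ConfigError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.eps <= 0:
            raise ConfigError("eps must be positive")
        if self.L < 0:
            raise ConfigError("L must be non-negative")
        if self.pooling not in ("mean", "sum", "max"):
            raise ConfigError(f"unknown pooling {self.pooling!r}")


@dataclass
class PackedMolecules:
    """One side (all solutes or all solvents) of a packed pair batch."""

    atoms: Tensor                 # (A, d) current atom embeddings
    edges: Tensor                 # (E, d) directed edge embeddings (2/bond)
    u: Tensor                     # (B, d) global embeddings, constant per round
    src: np.ndarray               # (E,) message source atom
    dst: np.ndarray               # (E,) message destination atom
    atom_graph: np.ndarray        # (A,) graph id per atom
    edge_graph: np.ndarray        # (E,)
    hyper_of_atom: np.ndarray     # (A,) hypernode id per atom (batch-global)
    hyper_graph: np.ndarray       # (C,) graph id per hypernode
    hyper_prior: np.ndarray       # (C,) bool
    hypernode_atoms: tuple[tuple[int, ...], ...]  # batch-global atom indices
    n_graphs: int

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_hyper(self) -> int:
        return len(self.hyper_graph)


@dataclass
class PairState:
    """Evolving embeddings of a batch of solute-solvent pairs."""

    solute: PackedMolecules
    solvent: PackedMolecules
    solute_hyper: Tensor | None = None    # (C1, d)
    solvent_hyper: Tensor | None = None   # (C2, d)
    solute_msg: Tensor | None = None      # (C1, d) attended messages
    solvent_msg: Tensor | None = None     # (C2, d)
    attention: Tensor | None = None       # (C1, C2) row-normalized, block-masked
    attention_rev: Tensor | None = None   # (C1, C2) column-normalized
    round: int = 0


class InteractionParams:
    """Untied per-round weights for the intramolecular edge/node update.

    The same weights serve solute and solvent: both are small organic
    molecules drawn from one vocabulary, so the encoder is shared and role
    asymmetry is carried entirely by the readout ordering.
    """

    NAMES = ("edge_nodes", "edge_edge", "edge_global",
             "node_self", "node_neigh", "node_global")

    def __init__(self, d: int, L: int, rng: np.random.Generator):
        self.d, self.L = d, L
        self.rounds: list[dict[str, Linear]] = [
            {name: Linear(d, d, rng) for name in self.NAMES} for _ in range(L)
        ]

    def parameters(self) -> list[Tensor]:
        out = []
        for rnd in self.rounds:
            for lin in rnd.values():
                out.extend(lin.parameters())
        return out


def pack_molecules(
    graphs: Sequence[MolecularGraph],
    hypergraphs: Sequence[Hypergraph],
    projector: FeatureProjector,
) -> PackedMolecules:
    """Pack one side of a pair batch into flat arrays and project to width d."""
    if len(graphs) != len(hypergraphs):
        raise InputError("graphs and hypergraphs must align")
    atom_raw, bond_raw, glob_raw = [], [], []
    src, dst, atom_graph, edge_graph = [], [], [], []
    hyper_of_atom, hyper_graph, hyper_prior = [], [], []
    hypernode_atoms: list[tuple[int, ...]] = []
    atom_off = hyper_off = 0
    for g_id, (graph, hg) in enumerate(zip(graphs, hypergraphs)):
        atom_raw.append(graph.atom_features)
        glob_raw.append(graph.global_features)
        atom_graph.extend([g_id] * graph.n_atoms)
        for (p, q), feat in zip(graph.bond_index, graph.bond_features):
            for a, b in ((p, q), (q, p)):  # undirected bond, bidirectional messages
                bond_raw.append(feat)
                src.append(atom_off + int(a))
                dst.append(atom_off + int(b))
                edge_graph.append(g_id)
        hyper_of_atom.extend(int(hg.atom_to_hypernode[i]) + hyper_off
                             for i in range(graph.n_atoms))
        hyper_graph.extend([g_id] * hg.n_hypernodes)
        hyper_prior.extend(bool(x) for x in hg.is_prior)
        hypernode_atoms.extend(tuple(atom_off + a for a in node)
                               for node in hg.hypernodes)
        atom_off += graph.n_atoms
        hyper_off += hg.n_hypernodes
    d = projector.target_dim
    atoms, edges, u = projector.project_arrays(
        np.concatenate(atom_raw, axis=0),
        np.asarray(bond_raw) if bond_raw else np.zeros((0, projector.bond.n_in)),
        np.asarray(glob_raw),
    )
    return PackedMolecules(
        atoms=atoms, edges=edges, u=u,
        src=np.asarray(src, dtype=np.intp), dst=np.asarray(dst, dtype=np.intp),
        atom_graph=np.asarray(atom_graph, dtype=np.intp),
        edge_graph=np.asarray(edge_graph, dtype=np.intp),
        hyper_of_atom=np.asarray(hyper_of_atom, dtype=np.intp),
        hyper_graph=np.asarray(hyper_graph, dtype=np.intp),
        hyper_prior=np.asarray(hyper_prior, dtype=bool),
        hypernode_atoms=tuple(hypernode_atoms),
        n_graphs=len(graphs),
    )


def edge_gates(edge_emb: Tensor, dst: np.ndarray, n_atoms: int,
               eps: float) -> Tensor:
    """Sigmoid edge gates normalized over each receiving atom's neighborhood.

    The ``eps`` in the denominator keeps every neighborhood's gate sum
    strictly below 1; as eps -> 0 the sums approach 1.
    """
    raw = edge_emb.sigmoid()
    denom = segment_sum(raw, dst, n_atoms)[dst] + eps
    return raw / denom


def intra_step(state: PairState, which: str, params: dict[str, Linear],
               config: NetConfig) -> PairState:
    """One intramolecular edge/node update on ``which`` ('solute'|'solvent')."""
    side: PackedMolecules = getattr(state, which)
    v, e, u = side.atoms, side.edges, side.u
    slope = config.leaky_slope
    if len(side.src):
        vsum = v[side.src] + v[side.dst]
        ue = u[side.edge_graph]
        e_new = e + (params["edge_nodes"](vsum) + params["edge_edge"](e)
                     + params["edge_global"](ue)).leaky_relu(slope)
        gate = edge_gates(e_new, side.dst, side.n_atoms, config.eps)
        neigh = segment_sum(gate * params["node_neigh"](v[side.src]),
                            side.dst, side.n_atoms)
    else:  # single heavy atom: empty neighborhood
        e_new = e
        neigh = constant(np.zeros((side.n_atoms, config.d)))
    ua = u[side.atom_graph]
    v_new = v + (params["node_self"](v) + neigh
                 + params["node_global"](ua)).leaky_relu(slope)
    return replace(state, **{which: replace(side, atoms=v_new, edges=e_new)})


def _pool(side: PackedMolecules, mode: str) -> Tensor:
    ids, n = side.hyper_of_atom, side.n_hyper
    if mode == "mean":
        return segment_mean(side.atoms, ids, n)
    if mode == "sum":
        return segment_sum(side.atoms, ids, n)
    # max with tie-averaged subgradient
    data = side.atoms.data
    mx = np.full((n, data.shape[1]), -np.inf)
    np.maximum.at(mx, ids, data)
    mask = (data == mx[ids]).astype(np.float64)
    counts = np.zeros((n, data.shape[1]))
    np.add.at(counts, ids, mask)
    weights = mask / counts[ids]
    return segment_sum(side.atoms * constant(weights), ids, n)


def pool_hypernodes(state: PairState, config: NetConfig) -> PairState:
    """Aggregate member-atom embeddings into hypernode embeddings."""
    return replace(
        state,
        solute_hyper=_pool(state.solute, config.pooling),
        solvent_hyper=_pool(state.solvent, config.pooling),
    )


def _masked_softmax(scores: Tensor, mask: np.ndarray, axis: int) -> Tensor:
    """Softmax of `scores` restricted to `mask` (block-diagonal pair structure)."""
    shifted = np.where(mask, scores.data, -np.inf)
    shift = shifted.max(axis=axis, keepdims=True)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    e = (scores - constant(shift)).exp() * constant(mask.astype(np.float64))
    denom = e.sum(axis=axis, keepdims=True)
    return e / denom


def cross_attention(state: PairState, config: NetConfig) -> PairState:
    """Hypernode co-attention; both directions use pre-update embeddings."""
    h1, h2 = state.solute_hyper, state.solvent_hyper
    if h1 is None or h2 is None:
        raise InputError("pool_hypernodes must run before cross_attention")
    if h1.shape[0] == 0 or h2.shape[0] == 0:
        raise InputError("cross attention requires at least one hypernode per side")
    mask = (state.solute.hyper_graph[:, None] == state.solvent.hyper_graph[None, :])
    scores = h1 @ h2.T
    if config.scale_scores:
        scores = scores * (1.0 / np.sqrt(config.d))
    if config.prior_bias:
        both_prior = np.outer(state.solute.hyper_prior, state.solvent.hyper_prior)
        scores = scores + constant(config.prior_bias * both_prior.astype(np.float64))
    alpha = _masked_softmax(scores, mask, axis=1)      # solute rows
    alpha_rev = _masked_softmax(scores, mask, axis=0)  # solvent columns
    return replace(
        state,
        solute_msg=alpha @ h2,
        solvent_msg=alpha_rev.T @ h1,
        attention=alpha,
        attention_rev=alpha_rev,
    )


def broadcast_update(state: PairState, config: NetConfig) -> PairState:
    """Mix each atom's embedding with its hypernode's attended message."""
    if config.gamma == 0.0:  # bit-exact identity; the no-exchange ablation
        return state
    if state.solute_msg is None or state.solvent_msg is None:
        raise InputError("cross_attention must run before broadcast_update")
    g = config.gamma
    new_sides = {}
    for which, msg in (("solute", state.solute_msg), ("solvent", state.solvent_msg)):
        side: PackedMolecules = getattr(state, which)
        atoms = side.atoms * (1.0 - g) + msg[side.hyper_of_atom] * g
        new_sides[which] = replace(side, atoms=atoms)
    return replace(state, **new_sides)


def run_rounds(state: PairState, params: InteractionParams,
               config: NetConfig) -> PairState:
    """Run the L alternating rounds; the final attention matrix is retained."""
    if params.L < config.L:
        raise ConfigError(f"parameters cover {params.L} rounds, config wants {config.L}")
    for layer in range(config.L):
        round_params = params.rounds[layer]
        state = intra_step(state, "solute", round_params, config)
        state = intra_step(state, "solvent", round_params, config)
        state = pool_hypernodes(state, config)
        state = cross_attention(state, config)
        state = broadcast_update(state, config)
        state = replace(state, round=state.round + 1)
    return state
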