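"""End-to-end solvation free-energy predictor.

Pipeline per batch of solute-solvent pairs: featurized graphs are decomposed
into vocabulary hypergraphs, projected to the embedding width, run through the
L alternating message-passing rounds, pooled into final hypernode embeddings,
gated by the information bottleneck, and read out.  The readout applies
set2set to each molecule's *gated* hypernode embeddings and concatenates
[solute readout | solvent readout]; routing the prediction exclusively
through the gated representations keeps the information bottleneck on-path
(closing a gate that matters must cost prediction accuracy), and the fixed
concatenation order encodes the asymmetric roles of the two molecules.  A
two-hidden-layer feedforward head with LeakyReLU and dropout produces the
scalar prediction in kcal/mol.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat, constant, no_grad, segment_mean, segment_sum
from .errors import CheckpointError, HypersolvError, InputError
from .gib import (GateState, GibConfig, gate_probabilities, inject_noise,
                  mi_upper_bound, molecule_moments, sample_relaxed_gates,
                  total_loss)
from .interaction import (InteractionParams, NetConfig, PackedMolecules,
                          PairState, pack_molecules, pool_hypernodes,
                          run_rounds)
from .molgraph import FeatureProjector, MolecularGraph, PairExample
from .nn import Linear, LSTMCell, dropout, segment_softmax
from .vocab import Hypergraph, SubgraphVocabulary, decompose

__all__ = ["ModelConfig", "SolvationModel", "ForwardResult", "EncodedBatch",
           "vocabulary_hash"]


@dataclass
class ModelConfig:
    net: NetConfig = field(default_factory=NetConfig)
    gib: GibConfig = field(default_factory=GibConfig)
    readout_steps: int = 3
    ffn_width: int = 1024
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.ffn_width < 1:
            raise HypersolvError("ffn_width must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise HypersolvError("dropout must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {"net": asdict(self.net), "gib": asdict(self.gib),
                "readout_steps": self.readout_steps, "ffn_width": self.ffn_width,
                "dropout": self.dropout, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(net=NetConfig(**d["net"]), gib=GibConfig(**d["gib"]),
                   readout_steps=d["readout_steps"], ffn_width=d["ffn_width"],
                   dropout=d["dropout"], seed=d["seed"])


def vocabulary_hash(vocab: SubgraphVocabulary) -> str:
    buf = "\n".join(
        json.dumps({"canonical_form": f.canonical_form, "size": f.size,
                    "frequency": f.frequency, "is_prior": f.is_prior,
                    "rank": f.rank}, sort_keys=True)
        for f in vocab.fragments
    )
    return hashlib.sha256(buf.encode()).hexdigest()


@dataclass
class EncodedBatch:
    """Pre-decomposed pairs, cached so training epochs skip re-featurization."""

    solute_graphs: list[MolecularGraph]
    solvent_graphs: list[MolecularGraph]
    solute_hgs: list[Hypergraph]
    solvent_hgs: list[Hypergraph]
    labels: np.ndarray | None

    def __len__(self) -> int:
        return len(self.solute_graphs)

    def subset(self, idx: Sequence[int]) -> "EncodedBatch":
        idx = list(idx)
        return EncodedBatch(
            [self.solute_graphs[i] for i in idx],
            [self.solvent_graphs[i] for i in idx],
            [self.solute_hgs[i] for i in idx],
            [self.solvent_hgs[i] for i in idx],
            None if self.labels is None else self.labels[idx],
        )


@dataclass
class ForwardResult:
    prediction: Tensor            # (B,)
    solute_gates: GateState
    solvent_gates: GateState
    attention: Tensor             # (C1, C2) block row-softmax
    attention_rev: Tensor         # (C1, C2) block column-softmax
    state: PairState
    bound_solute: Tensor          # (B,)
    bound_solvent: Tensor         # (B,)


class SolvationModel:
    """Trainable hypergraph predictor of solvation Gibbs free energy."""

    def __init__(self, config: ModelConfig, vocab: SubgraphVocabulary):
        self.config = config
        self.vocab = vocab
        self.vocab_hash = vocabulary_hash(vocab)
        rng = np.random.default_rng(config.seed)
        d = config.net.d
        self.projector = FeatureProjector(d, rng)
        self.interaction = InteractionParams(d, config.net.L, rng)
        self.gate_fc = Linear(d, 1, rng)
        self.set2set_lstm = LSTMCell(2 * d, d, rng)
        self.head = [
            Linear(4 * d, config.ffn_width, rng),
            Linear(config.ffn_width, config.ffn_width, rng),
            Linear(config.ffn_width, 1, rng),
        ]

    # -- parameters --------------------------------------------------------
    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for i, p in enumerate(self.projector.parameters()):
            out.append((f"projector.{i}", p))
        for i, p in enumerate(self.interaction.parameters()):
            out.append((f"interaction.{i}", p))
        for i, p in enumerate(self.gate_fc.parameters()):
            out.append((f"gate_fc.{i}", p))
        for i, p in enumerate(self.set2set_lstm.parameters()):
            out.append((f"set2set.{i}", p))
        for j, lin in enumerate(self.head):
            for i, p in enumerate(lin.parameters()):
                out.append((f"head.{j}.{i}", p))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    # -- data preparation --------------------------------------------------
    def encode_pairs(self, pairs: Sequence[PairExample]) -> EncodedBatch:
        """Decompose pairs against the vocabulary (cached upstream of epochs)."""
        labels = [p.label for p in pairs]
        has_labels = all(l is not None for l in labels)
        return EncodedBatch(
            [p.solute for p in pairs],
            [p.solvent for p in pairs],
            [decompose(p.solute, self.vocab) for p in pairs],
            [decompose(p.solvent, self.vocab) for p in pairs],
            np.array(labels, dtype=np.float64) if has_labels else None,
        )

    # -- forward -----------------------------------------------------------
    def _set2set(self, x: Tensor, ids: np.ndarray, n: int) -> Tensor:
        """Order-invariant iterative attention readout over a row set."""
        d = self.config.net.d
        q_star = constant(np.zeros((n, 2 * d)))
        h = constant(np.zeros((n, d)))
        c = constant(np.zeros((n, d)))
        for _ in range(self.config.readout_steps):
            h, c = self.set2set_lstm(q_star, h, c)
            scores = (x * h[ids]).sum(axis=1)
            att = segment_softmax(scores, ids, n)
            r = segment_sum(x * att.reshape(-1, 1), ids, n)
            q_star = concat([h, r], axis=1)
        return q_star

    def _gate_side(self, hyper: Tensor, side: PackedMolecules, mode: str,
                   rng: np.random.Generator | None) -> tuple[GateState, Tensor]:
        n = side.n_graphs
        ids = side.hyper_graph
        p = gate_probabilities(hyper, self.gate_fc)
        if mode == "train":
            if rng is None:
                raise InputError("training-mode forward needs an RNG")
            lam = sample_relaxed_gates(p, self.config.gib.temperature, rng)
        else:
            lam = p
        mu, sigma = molecule_moments(hyper, ids, n)
        z = inject_noise(hyper, lam, mu, sigma, ids,
                         rng if mode == "train" else None)
        bound = mi_upper_bound(lam, hyper, mu, sigma, ids, n)
        m = np.bincount(ids, minlength=n)
        return GateState(p, lam, z, mu, sigma, ids, m), bound

    def forward(self, batch: EncodedBatch | Sequence[PairExample],
                mode: str = "eval",
                rng: np.random.Generator | None = None) -> ForwardResult:
        if mode not in ("train", "eval"):
            raise InputError(f"unknown mode {mode!r}")
        if not isinstance(batch, EncodedBatch):
            batch = self.encode_pairs(batch)
        if len(batch) == 0:
            raise InputError("empty batch")
        cfg = self.config
        solute = pack_molecules(batch.solute_graphs, batch.solute_hgs, self.projector)
        solvent = pack_molecules(batch.solvent_graphs, batch.solvent_hgs, self.projector)
        state = PairState(solute=solute, solvent=solvent)
        state = run_rounds(state, self.interaction, cfg.net)
        state = pool_hypernodes(state, cfg.net)

        gates1, bound1 = self._gate_side(state.solute_hyper, state.solute, mode, rng)
        gates2, bound2 = self._gate_side(state.solvent_hyper, state.solvent, mode, rng)

        n = solute.n_graphs
        readout = concat(
            [
                self._set2set(gates1.z, solute.hyper_graph, n),
                self._set2set(gates2.z, solvent.hyper_graph, n),
            ],
            axis=1,
        )
        training = mode == "train"
        x = readout
        for lin in self.head[:-1]:
            x = lin(x).leaky_relu(cfg.net.leaky_slope)
            x = dropout(x, cfg.dropout, rng, training) if training else x
        pred = self.head[-1](x).reshape(-1)
        if not np.all(np.isfinite(pred.data)):
            raise HypersolvError("non-finite prediction from the readout head")
        attn = state.attention
        if attn is None:  # L == 0: no attention was ever computed
            attn = constant(np.zeros((solute.n_hyper, solvent.n_hyper)))
        attn_rev = state.attention_rev
        if attn_rev is None:
            attn_rev = constant(np.zeros((solute.n_hyper, solvent.n_hyper)))
        return ForwardResult(pred, gates1, gates2, attn, attn_rev, state,
                             bound1, bound2)

    def loss(self, result: ForwardResult, labels: np.ndarray,
             beta: float | None = None) -> Tensor:
        beta = self.config.gib.beta if beta is None else beta
        return total_loss(result.prediction, labels,
                          result.bound_solute, result.bound_solvent, beta)

    def predict_batch(self, pairs: Sequence[PairExample] | EncodedBatch,
                      batch_size: int = 256) -> np.ndarray:
        """Order-preserving eval-mode predictions (kcal/mol)."""
        if not isinstance(pairs, EncodedBatch):
            pairs = self.encode_pairs(pairs)
        if len(pairs) == 0:
            return np.zeros(0)
        out = []
        with no_grad():
            for a in range(0, len(pairs), batch_size):
                sub = pairs.subset(range(a, min(a + batch_size, len(pairs))))
                out.append(self.forward(sub, mode="eval").prediction.data)
        return np.concatenate(out)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: weights + config + vocabulary hash."""
        arrays = {name: p.data for name, p in self.named_parameters()}
        meta = json.dumps({"config": self.config.to_dict(),
                           "vocab_hash": self.vocab_hash,
                           "seed": self.config.seed})
        with open(path, "wb") as fh:  # explicit handle: no .npz suffix games
            np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                     **arrays)

    @classmethod
    def load(cls, path: str | Path, vocab: SubgraphVocabulary) -> "SolvationModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            config = ModelConfig.from_dict(meta["config"])
            model = cls(config, vocab)
            if model.vocab_hash != meta["vocab_hash"]:
                raise CheckpointError(
                    "checkpoint was trained against a different vocabulary "
                    f"(hash {meta['vocab_hash'][:12]}... != {model.vocab_hash[:12]}...)"
                )
            for name, p in model.named_parameters():
                if name not in data:
                    raise CheckpointError(f"checkpoint missing parameter {name}")
                if data[name].shape != p.data.shape:
                    raise CheckpointError(
                        f"parameter {name} has shape {data[name].shape}, "
                        f"model expects {p.data.shape}"
                    )
                p.data = data[name].astype(np.float64)
        return model
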