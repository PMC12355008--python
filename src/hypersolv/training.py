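"""Optimization loop, evaluation metrics and dataset splitting.

Training minimizes the composite objective (squared error plus the
beta-weighted information-bottleneck bounds) with Adam under a cosine
annealing schedule, tracks validation MAE, stops early after ``patience``
epochs without improvement, and restores the best-validation weights.
Everything is driven by explicit seeds: two runs with the same data, configs
and seeds produce bit-identical histories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .errors import HypersolvError, InputError
from .model import EncodedBatch, ModelConfig, SolvationModel
from .molgraph import PairExample
from .nn import Adam, cosine_lr
from .vocab import SubgraphVocabulary

log = logging.getLogger(__name__)

__all__ = ["TrainConfig", "EvalReport", "split_dataset", "train", "evaluate",
           "save_history"]


@dataclass
class TrainConfig:
    batch_size: int = 128
    lr_init: float = 1e-4
    lr_min: float = 1e-6
    schedule: str = "cosine"       # cosine | step
    step_decay: float = 0.5        # per-interval factor for the step schedule
    step_every: int = 100
    patience: int = 150
    max_epochs: int = 1000
    split: object = "random"       # "random" | ("solvent_holdout", [...]) | ("scaffold_holdout", [...])
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise InputError("patience must not exceed max_epochs")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise InputError("split fractions must sum to 1")
        if self.schedule not in ("cosine", "step"):
            raise InputError(f"unknown schedule {self.schedule!r}")


@dataclass
class EvalReport:
    mae: float
    rmse: float
    n: int
    r2: float
    per_group: dict = field(default_factory=dict)


def _canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else smiles


def split_dataset(
    pairs: Sequence[PairExample],
    split_spec: object = "random",
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> tuple[list[PairExample], list[PairExample], list[PairExample]]:
    """Split into (train, valid, test).

    ``random`` shuffles with the seed and cuts by ``fractions``.  Holdout modes
    place every matching pair in the test set only, then cut the remainder
    into train/valid at the train:valid ratio; the held-out solvents or
    scaffolds therefore never leak into train or valid.
    """
    pairs = list(pairs)
    if not pairs:
        raise InputError("empty dataset")
    rng = np.random.default_rng(seed)
    if split_spec == "random":
        idx = rng.permutation(len(pairs))
        n_train = int(fractions[0] * len(pairs))
        n_valid = int(fractions[1] * len(pairs))
        train = [pairs[i] for i in idx[:n_train]]
        valid = [pairs[i] for i in idx[n_train:n_train + n_valid]]
        test = [pairs[i] for i in idx[n_train + n_valid:]]
        return train, valid, test

    mode, patterns = split_spec
    if mode == "solvent_holdout":
        held = {_canonical(s) for s in patterns}
        in_test = [(_canonical(p.solvent.smiles) in held) for p in pairs]
    elif mode == "scaffold_holdout":
        queries = [Chem.MolFromSmarts(s) or Chem.MolFromSmiles(s) for s in patterns]
        if any(q is None for q in queries):
            raise InputError(f"unparsable scaffold pattern in {patterns}")
        in_test = []
        for p in pairs:
            mol = Chem.MolFromSmiles(p.solute.smiles)
            in_test.append(any(mol.HasSubstructMatch(q) for q in queries))
    else:
        raise InputError(f"unknown split mode {mode!r}")

    test = [p for p, t in zip(pairs, in_test) if t]
    rest = [p for p, t in zip(pairs, in_test) if not t]
    if not rest:
        raise InputError("holdout list covers the entire dataset")
    idx = rng.permutation(len(rest))
    ratio = fractions[0] / (fractions[0] + fractions[1])
    n_train = int(round(ratio * len(rest)))
    train = [rest[i] for i in idx[:n_train]]
    valid = [rest[i] for i in idx[n_train:]]
    return train, valid, test


def _lr_for_epoch(cfg: TrainConfig, epoch: int) -> float:
    if cfg.schedule == "cosine":
        return cosine_lr(epoch, cfg.max_epochs, cfg.lr_init, cfg.lr_min)
    return cfg.lr_init * cfg.step_decay ** (epoch // cfg.step_every)


def train(
    pairs: Sequence[PairExample],
    vocab: SubgraphVocabulary,
    model_config: ModelConfig,
    train_config: TrainConfig,
    valid_pairs: Sequence[PairExample] | None = None,
) -> tuple[SolvationModel, list[dict]]:
    """Train a model; returns it with best-validation weights restored.

    With ``valid_pairs=None`` the input is split internally by
    ``train_config.split`` and the test portion is simply not used here.
    """
    if valid_pairs is None:
        train_pairs, valid_list, _ = split_dataset(
            pairs, train_config.split, train_config.seed, train_config.fractions)
    else:
        train_pairs, valid_list = list(pairs), list(valid_pairs)
    if not train_pairs or not valid_list:
        raise InputError("train and validation sets must be non-empty")

    model = SolvationModel(model_config, vocab)
    encoded_train = model.encode_pairs(train_pairs)
    encoded_valid = model.encode_pairs(valid_list)
    if encoded_train.labels is None or encoded_valid.labels is None:
        raise InputError("training requires labels on every pair")

    opt = Adam(model.parameters(), lr=train_config.lr_init)
    shuffle_rng = np.random.default_rng(train_config.seed)
    noise_rng = np.random.default_rng(train_config.seed + 1)

    best_mae = np.inf
    best_weights: list[np.ndarray] | None = None
    stale = 0
    history: list[dict] = []
    n = len(encoded_train)

    for epoch in range(1, train_config.max_epochs + 1):
        lr = _lr_for_epoch(train_config, epoch - 1)
        order = shuffle_rng.permutation(n)
        losses = []
        for a in range(0, n, train_config.batch_size):
            batch = encoded_train.subset(order[a:a + train_config.batch_size])
            result = model.forward(batch, mode="train", rng=noise_rng)
            loss = model.loss(result, batch.labels)
            if not np.isfinite(loss.data):
                if best_weights is not None:
                    for p, w in zip(model.parameters(), best_weights):
                        p.data = w.copy()
                raise HypersolvError(
                    f"training diverged at epoch {epoch}; last finite epoch: "
                    f"{history[-1]['epoch'] if history else 'none'}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            losses.append(float(loss.data))

        valid_pred = model.predict_batch(encoded_valid)
        err = valid_pred - encoded_valid.labels
        valid_mae = float(np.mean(np.abs(err)))
        valid_rmse = float(np.sqrt(np.mean(err**2)))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "valid_mae": valid_mae, "valid_rmse": valid_rmse,
                        "lr": lr})
        if valid_mae < best_mae:
            best_mae = valid_mae
            best_weights = [p.data.copy() for p in model.parameters()]
            stale = 0
        else:
            stale += 1
            if stale >= train_config.patience:
                log.info("early stop at epoch %d (no improvement for %d epochs)",
                         epoch, stale)
                break

    if best_weights is not None:
        for p, w in zip(model.parameters(), best_weights):
            p.data = w
    return model, history


def evaluate(
    pairs: Sequence[PairExample] | EncodedBatch,
    model: SolvationModel,
    group_by: object = None,
) -> EvalReport:
    """MAE / RMSE / R^2 on labelled pairs.

    ``group_by`` may be ``"solvent"`` (one group per solvent SMILES) or
    ``("scaffold", patterns)`` (one group per matching substructure pattern;
    a solute matching several patterns counts in each).
    """
    if isinstance(pairs, EncodedBatch):
        encoded = pairs
        pairs = None
    else:
        pairs = list(pairs)
        if any(p.label is None for p in pairs):
            raise InputError("evaluate requires labels on every pair")
        encoded = model.encode_pairs(pairs)
    if encoded.labels is None:
        raise InputError("evaluate requires labels on every pair")
    pred = model.predict_batch(encoded)
    err = pred - encoded.labels
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    denom = float(np.var(encoded.labels))
    r2 = 1.0 - float(np.mean(err**2)) / denom if denom > 0 else float("nan")
    per_group: dict[str, dict] = {}
    if group_by is not None and pairs is not None:
        if group_by == "solvent":
            groups = {s: [i for i, p in enumerate(pairs)
                          if p.solvent.smiles == s]
                      for s in sorted({p.solvent.smiles for p in pairs})}
        elif isinstance(group_by, tuple) and group_by[0] == "scaffold":
            groups = {}
            for patt in group_by[1]:
                q = Chem.MolFromSmarts(patt) or Chem.MolFromSmiles(patt)
                if q is None:
                    raise InputError(f"unparsable scaffold pattern {patt!r}")
                groups[patt] = [
                    i for i, p in enumerate(pairs)
                    if Chem.MolFromSmiles(p.solute.smiles).HasSubstructMatch(q)
                ]
        else:
            raise InputError(f"unknown group_by {group_by!r}")
        for key, sel in groups.items():
            if not sel:
                continue
            g_err = err[sel]
            per_group[key] = {"mae": float(np.mean(np.abs(g_err))),
                              "rmse": float(np.sqrt(np.mean(g_err**2))),
                              "n": len(sel)}
    return EvalReport(mae=mae, rmse=rmse, n=len(encoded), r2=r2,
                      per_group=per_group)


def save_history(history: Sequence[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in history:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
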