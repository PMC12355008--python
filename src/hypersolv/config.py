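"""Single-source-of-truth run configuration.

A run config is a YAML mapping with up to three sections — ``model``,
``train`` and ``synthetic`` — whose keys mirror the corresponding dataclasses.
Unknown keys are rejected so typos fail loudly, and every command echoes the
fully resolved config into its output directory for reproducibility.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .gib import GibConfig
from .interaction import NetConfig
from .model import ModelConfig
from .synthetic import PlantedRule, SyntheticSpec
from .training import TrainConfig

__all__ = ["load_run_config", "build_model_config", "build_train_config",
           "build_synthetic_spec", "dump_run_config"]


def _strict(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in section {where!r}; "
                          f"allowed: {sorted(allowed)}")
    return cls(**data)


def load_run_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - {"model", "train", "synthetic"}
    if unknown:
        raise ConfigError(f"unknown top-level sections {sorted(unknown)}")
    # validate every present section eagerly so typos fail loudly
    if "model" in data:
        build_model_config(data)
    if "train" in data:
        build_train_config(data)
    if "synthetic" in data:
        build_synthetic_spec(data)
    return data


def build_model_config(cfg: dict, **overrides) -> ModelConfig:
    section = dict(cfg.get("model", {}))
    net = _strict(NetConfig, {**section.pop("net", {}),
                              **overrides.pop("net", {})}, "model.net")
    gib = _strict(GibConfig, {**section.pop("gib", {}),
                              **overrides.pop("gib", {})}, "model.gib")
    section.update({k: v for k, v in overrides.items() if v is not None})
    allowed = {f.name for f in fields(ModelConfig)} - {"net", "gib"}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in section 'model'")
    return ModelConfig(net=net, gib=gib, **section)


def build_train_config(cfg: dict, **overrides) -> TrainConfig:
    section = dict(cfg.get("train", {}))
    section.update({k: v for k, v in overrides.items() if v is not None})
    if isinstance(section.get("split"), list):
        section["split"] = tuple(section["split"])
    if isinstance(section.get("fractions"), list):
        section["fractions"] = tuple(section["fractions"])
    return _strict(TrainConfig, section, "train")


def build_synthetic_spec(cfg: dict, **overrides) -> SyntheticSpec:
    section = dict(cfg.get("synthetic", {}))
    section.update({k: v for k, v in overrides.items() if v is not None})
    if "rules" in section:
        section["rules"] = tuple(
            r if isinstance(r, PlantedRule) else PlantedRule(**r)
            for r in section["rules"]
        )
    for key in ("size_range", "elements", "element_weights"):
        if isinstance(section.get(key), list):
            section[key] = tuple(section[key])
    return _strict(SyntheticSpec, section, "synthetic")


def dump_run_config(model_cfg: ModelConfig | None, train_cfg: TrainConfig | None,
                    spec: SyntheticSpec | None, path: str | Path) -> None:
    """Echo the resolved configuration of a run."""
    out: dict = {}
    if model_cfg is not None:
        out["model"] = model_cfg.to_dict()
    if train_cfg is not None:
        d = dict(train_cfg.__dict__)
        if isinstance(d.get("split"), tuple):
            d["split"] = list(d["split"])
        d["fractions"] = list(d["fractions"])
        out["train"] = d
    if spec is not None:
        d = dict(spec.__dict__)
        d["rules"] = [dict(solute_motif=r.solute_motif, solvent_motif=r.solvent_motif,
                           weight=r.weight) for r in d["rules"]]
        d["size_range"] = list(d["size_range"])
        d["elements"] = list(d["elements"])
        d["element_weights"] = list(d["element_weights"])
        out["synthetic"] = d
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))
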