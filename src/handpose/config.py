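"""Run configuration: YAML files merged with command-line overrides.

Precedence is defaults < file < overrides; unknown keys are rejected so
typos fail loudly.  Defaults reproduce the shipped training recipe
(Adam, lr 0.001, batch 20, plateau decay 0.7/patience 3, sigma 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .nn import ModelConfig
from .training import AugmentParams, TrainConfig, LossWeights

__all__ = ["RunConfig", "load_config", "DEFAULT_EPOCHS"]

# Epoch presets per dataset flavor (varied-pose vs cyclic tapping data).
DEFAULT_EPOCHS = {"pose": 25, "tap": 35}


@dataclass
class RunConfig:
    model: ModelConfig
    train: TrainConfig
    augment: AugmentParams
    loss: LossWeights
    cube_mm: float = 250.0

    def describe(self) -> str:
        return yaml.safe_dump({
            "model": {f.name: getattr(self.model, f.name) for f in fields(ModelConfig)},
            "train": {f.name: getattr(self.train, f.name) for f in fields(TrainConfig)},
            "augment": {f.name: list(getattr(self.augment, f.name)) for f in fields(AugmentParams)},
            "loss": {f.name: getattr(self.loss, f.name) for f in fields(LossWeights)},
            "cube_mm": self.cube_mm,
        }, sort_keys=False)


def _build(cls, defaults: dict, section: dict, label: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown {label} config keys: {sorted(unknown)}")
    merged = {**defaults, **section}
    if cls is AugmentParams:
        merged = {k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in merged.items()}
    return cls(**merged)


def load_config(path=None, overrides: dict | None = None, J: int = 6) -> RunConfig:
    """Resolve a RunConfig from an optional YAML file and override mapping.

    ``overrides`` uses dotted section keys, e.g. ``{"train.lr": 0.01}``.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
    sections = {"model": {}, "train": {}, "augment": {}, "loss": {}}
    top = {}
    for key, val in data.items():
        if key in sections:
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            sections[key].update(val)
        elif key == "cube_mm":
            top["cube_mm"] = float(val)
        else:
            raise ValueError(f"unknown config key: {key!r}")
    for key, val in (overrides or {}).items():
        if key == "cube_mm":
            top["cube_mm"] = float(val)
            continue
        if "." not in key:
            raise ValueError(f"unknown config key: {key!r}")
        section, name = key.split(".", 1)
        if section not in sections:
            raise ValueError(f"unknown config section: {section!r}")
        sections[section][name] = val

    model = _build(ModelConfig, {"J": J}, sections["model"], "model")
    train = _build(TrainConfig, {}, sections["train"], "train")
    augment = _build(AugmentParams, {}, sections["augment"], "augment")
    loss = _build(LossWeights, {}, sections["loss"], "loss")
    return RunConfig(model=model, train=train, augment=augment, loss=loss,
                     cube_mm=top.get("cube_mm", 250.0))
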