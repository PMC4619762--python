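"""YAML configuration handling with validation.

One plain-text file holds the three configurable blocks::

    params:   # unit-dynamics constants (ModelParams fields)
      alpha: 0.2
    train:    # learning-run settings (TrainConfig fields)
      task: tracing
      eta: 0.02
    arch:     # keyword overrides for the architecture builder
      grid: 5
    curriculum:   # keyword overrides for the task's curriculum factory
      max_length: 5

An empty (or missing) file yields the full defaults.  Every violated
constraint is reported with the offending field name.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .params import ModelParams
from .training import TrainConfig


class ConfigError(ValueError):
    pass


def _build(cls, block: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ConfigError(f"{name}: unknown field(s) {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def load_config(path: str | Path | None) -> dict:
    """Load and validate a run configuration.

    Returns ``{"params": ModelParams, "train": TrainConfig,
    "arch": dict, "curriculum": dict}`` with defaults filled in.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    unknown = set(raw) - {"params", "train", "arch", "curriculum"}
    if unknown:
        raise ConfigError(f"unknown config section(s) {sorted(unknown)}")
    prm = _build(ModelParams, raw.get("params") or {}, "params")
    train = _build(TrainConfig, raw.get("train") or {}, "train")
    try:
        train.validate(prm)
    except ValueError as exc:
        raise ConfigError(f"train: {exc}") from exc
    return {
        "params": prm,
        "train": train,
        "arch": dict(raw.get("arch") or {}),
        "curriculum": dict(raw.get("curriculum") or {}),
    }


def config_to_dict(cfg: dict) -> dict:
    """Serializable snapshot of a validated configuration."""
    return {
        "params": dataclasses.asdict(cfg["params"]),
        "train": dataclasses.asdict(cfg["train"]),
        "arch": dict(cfg["arch"]),
        "curriculum": dict(cfg["curriculum"]),
    }


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
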