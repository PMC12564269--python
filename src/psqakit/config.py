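"""Experiment configuration: one YAML file with dotted-path CLI overrides."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .nn.model import NetworkConfig
from .synth import SimConfig
from .train import TrainConfig


@dataclass
class ExperimentConfig:
    """Bundle of simulator, network and training configuration plus paths."""

    sim: SimConfig = field(default_factory=SimConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    dataset_path: str = "dataset.h5"
    split_path: str = "split.csv"
    run_dir: str = "run"
    sweep_r: tuple[float, ...] = ()
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "train": self.train.to_dict(),
            "network": dataclasses.asdict(self.network),
            "dataset_path": self.dataset_path,
            "split_path": self.split_path,
            "run_dir": self.run_dir,
            "sweep_r": list(self.sweep_r),
            "seed": self.seed,
        }


class ConfigError(ValueError):
    """Raised on schema violations, naming the offending field."""


def _coerce_into(cls, data: dict, path: str):
    field_types = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in field_types:
            raise ConfigError(f"unknown field {path}{key}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {path.rstrip('.') or 'root'}: {exc}") from exc


def config_from_dict(data: dict) -> ExperimentConfig:
    data = dict(data or {})
    sections = {}
    for name, cls in (("sim", SimConfig), ("train", TrainConfig),
                      ("network", NetworkConfig)):
        sections[name] = _coerce_into(cls, data.pop(name, {}), f"{name}.")
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    extra = set(data) - known
    if extra:
        raise ConfigError(f"unknown field {sorted(extra)[0]}")
    if "sweep_r" in data and isinstance(data["sweep_r"], list):
        data["sweep_r"] = tuple(data["sweep_r"])
    return ExperimentConfig(**sections, **data)


def apply_overrides(data: dict, overrides: list[str]) -> dict:
    """Apply ``a.b.c=value`` overrides (YAML-parsed values) to a config
    dict, in order."""
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form key=value")
        key, raw = item.split("=", 1)
        value = yaml.safe_load(raw)
        node: Any = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
            if not isinstance(node, dict):
                raise ConfigError(f"cannot descend into {part!r} of {key!r}")
        node[parts[-1]] = value
    return data


def load_config(path: str, overrides: list[str] | None = None
                ) -> ExperimentConfig:
    with open(path, "r", encoding="utf-8") as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    if overrides:
        data = apply_overrides(data, list(overrides))
    return config_from_dict(data)
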