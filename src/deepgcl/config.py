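"""YAML-backed experiment configuration.

An experiment config bundles the trainer settings with the data-module
keys (hop count, target-edge exclusion, fingerprint kind).  Unknown keys
are rejected so typos fail fast.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .data_io import ConfigError
from .fusion_trainer import LossWeights, TrainConfig


@dataclass
class DataConfig:
    hop: int = 2
    exclude_target_edge: bool = True
    fingerprint: str = "maccs"
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self) -> None:
        if self.hop < 1:
            raise ConfigError("hop must be >= 1")
        self.split_ratios = tuple(self.split_ratios)


@dataclass
class ExperimentConfig:
    data: DataConfig = field(default_factory=DataConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_dict(cls, payload: dict) -> "ExperimentConfig":
        payload = dict(payload or {})
        data_kwargs = payload.pop("data", {}) or {}
        train_kwargs = payload.pop("train", {}) or {}
        if payload:
            raise ConfigError(f"unknown top-level config keys: {sorted(payload)}")
        _check_keys(DataConfig, data_kwargs)
        weights_kwargs = train_kwargs.pop("weights", None)
        _check_keys(TrainConfig, train_kwargs, skip=("weights",))
        if weights_kwargs is not None:
            train_kwargs["weights"] = LossWeights(**weights_kwargs)
        for key in ("sub_widths", "mol_widths"):
            if key in train_kwargs:
                train_kwargs[key] = tuple(train_kwargs[key])
        return cls(data=DataConfig(**data_kwargs), train=TrainConfig(**train_kwargs))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _check_keys(cls, kwargs: dict, skip: tuple[str, ...] = ()) -> None:
    allowed = {f.name for f in fields(cls)} | set(skip)
    unknown = set(kwargs) - allowed
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
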