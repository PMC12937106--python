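"""Run configuration: one YAML file describing a full pipeline run.

Blocks mirror the pipeline stages (system, graph, model, training, biasing,
loop, seeds, output).  Unknown keys are rejected so typos fail loudly;
defaults are materialized at load time so a saved provenance record always
shows the complete effective configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .model import ModelConfig
from .systems import SystemSpec
from .training import LoopSettings, TrainSettings

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Unknown keys or invalid values in a run configuration."""


_DEFAULT_SEEDS = {"data": 100, "train": 0, "sample": 5, "analysis": 9}


@dataclass
class RunConfig:
    system: dict
    graph: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    biasing: dict = field(default_factory=dict)
    loop: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        seeds = dict(_DEFAULT_SEEDS)
        seeds.update(self.seeds)
        unknown = set(self.seeds) - set(_DEFAULT_SEEDS)
        if unknown:
            raise ConfigError(f"unknown seed names {sorted(unknown)}")
        self.seeds = seeds
        _check_keys(self.system, {"dimensionality", "potential_id", "parameters",
                                  "beta", "masses"}, "system")
        _check_keys(self.graph, {"r_cut", "delta_b", "enforce_reacting_edges",
                                 "truncate"}, "graph")
        _check_keys(self.model, {f.name for f in fields(ModelConfig)}, "model")
        _check_keys(self.training, {f.name for f in fields(TrainSettings)},
                    "training")
        _check_keys(self.biasing, {"kernel_width", "gamma", "epsilon_floor",
                                   "deposition_stride"}, "biasing")
        _check_keys(self.loop, {f.name for f in fields(LoopSettings)} - {"train", "bias"},
                    "loop")

    def system_spec(self) -> SystemSpec:
        return SystemSpec(**self.system)

    def model_config(self) -> ModelConfig:
        kwargs = dict(self.model)
        if "readout_widths" in kwargs:
            kwargs["readout_widths"] = tuple(kwargs["readout_widths"])
        return ModelConfig(**kwargs)

    def train_settings(self) -> TrainSettings:
        return TrainSettings(seed=self.seeds["train"], **self.training)

    def loop_settings(self) -> LoopSettings:
        return LoopSettings(train=self.train_settings(), bias=dict(self.biasing),
                            seed=self.seeds["train"], **self.loop)

    def as_dict(self) -> dict:
        return asdict(self)


def _check_keys(block: dict, allowed: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {name!r} block: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    if "system" not in raw:
        raise ConfigError("config requires a 'system' block")
    return RunConfig(**raw)
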