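"""Experiment configuration: schema-validated nested YAML configs.

A config file mirrors the nested dataclass tree below; unknown keys are
rejected with the offending field path so typos fail before any compute.
All defaults are embedded here and a fully resolved copy is dumped next to
every experiment's outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import yaml

from .env import Arena, MotionParams, SelfMotionSpec
from .maps import SMCSpec

__all__ = ["ExperimentConfig", "load_config", "dump_config", "config_hash"]


@dataclass(frozen=True)
class HierarchyConfig:
    smallest_period: float = 30.0
    scale_factor: float = math.sqrt(math.e)
    n_modules: int = 2

    def __post_init__(self) -> None:
        if self.scale_factor <= 1 or self.smallest_period <= 0 or self.n_modules < 1:
            raise ValueError("invalid hierarchy configuration")


@dataclass(frozen=True)
class PopulationConfig:
    cells_per_module: int = 64
    n_smc: int = 64
    n_hidden: int = 256
    smc_correlation_length: float = 10.0

    def __post_init__(self) -> None:
        if min(self.cells_per_module, self.n_smc, self.n_hidden) < 1:
            raise ValueError("population sizes must be positive")


@dataclass(frozen=True)
class TrainingConfig:
    variant: str = "GC_ONLY"
    r_mask: float = 0.0
    traj_duration: float = 5.0
    batch_size: int = 16
    n_steps: int = 1500
    learning_rate: float = 1e-3
    noise_sigma: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_mask <= 1.0:
            raise ValueError("r_mask must lie in [0, 1]")


@dataclass(frozen=True)
class PlanningConfig:
    mode: str = "analytic"         # analytic | markov
    n_phase_bins: int = 16
    step_fraction: float = 0.5
    tol: float = 1.0
    max_steps: int = 200


@dataclass(frozen=True)
class AnalysisConfig:
    min_rate: float = 0.01
    min_sic: float = 3.0
    min_cells_for_decoding: int = 10
    query_steps: int = 100


@dataclass(frozen=True)
class ExperimentConfig:
    arena: Arena = field(default_factory=Arena)
    motion: MotionParams = field(default_factory=MotionParams)
    selfmotion: SelfMotionSpec = field(default_factory=SelfMotionSpec)
    hierarchy: HierarchyConfig = field(default_factory=HierarchyConfig)
    populations: PopulationConfig = field(default_factory=PopulationConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    planning: PlanningConfig = field(default_factory=PlanningConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    duration: float = 5.0
    out_dir: str = "runs"

    def world_kwargs(self) -> dict:
        from .maps import SMCSpec

        return dict(
            arena=self.arena,
            motion=self.motion,
            selfmotion=self.selfmotion,
            n_modules=self.hierarchy.n_modules,
            cells_per_module=self.populations.cells_per_module,
            smallest_period=self.hierarchy.smallest_period,
            scale_factor=self.hierarchy.scale_factor,
            smc_spec=SMCSpec(
                n_cells=self.populations.n_smc,
                correlation_length=self.populations.smc_correlation_length,
            ),
        )


def _from_mapping(cls, data, path=""):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        key = sorted(unknown)[0]
        raise ValueError(f"unknown config key: {path}{key}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = _NESTED.get((cls, name))
        if sub is not None:
            kwargs[name] = _from_mapping(sub, value, path=f"{path}{name}.")
        else:
            kwargs[name] = tuple(value) if isinstance(value, list) else value
    return cls(**kwargs)


_NESTED = {
    (ExperimentConfig, "arena"): Arena,
    (ExperimentConfig, "motion"): MotionParams,
    (ExperimentConfig, "selfmotion"): SelfMotionSpec,
    (ExperimentConfig, "hierarchy"): HierarchyConfig,
    (ExperimentConfig, "populations"): PopulationConfig,
    (ExperimentConfig, "training"): TrainingConfig,
    (ExperimentConfig, "planning"): PlanningConfig,
    (ExperimentConfig, "analysis"): AnalysisConfig,
}


def load_config(path_or_mapping) -> ExperimentConfig:
    """Load and validate a config file (or an already-parsed mapping)."""
    if isinstance(path_or_mapping, dict):
        data = path_or_mapping
    else:
        with open(path_or_mapping) as fh:
            data = yaml.safe_load(fh) or {}
    return _from_mapping(ExperimentConfig, data)


def _to_plain(obj):
    import numpy as np

    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def dump_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(_to_plain(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
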