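"""Run configuration: JSON/YAML loading, validation, seed fan-out.

A run is driven by a single config file with one block per pipeline stage.
Unknown keys are rejected with the offending key path so typos fail loudly.
The master ``seed`` fans out to per-stage seeds through
``numpy.random.SeedSequence([master, stage_index])``, so stages are
statistically independent yet each is a pure function of the master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

__all__ = ["RunConfig", "PathsConfig", "load_config", "stage_seed", "config_hash"]

#: stable stage indices for seed derivation
STAGES = {
    "simulate": 0,
    "attitude": 1,
    "pretrain": 2,
    "train_s1": 3,
    "train_s2": 4,
    "train_mcff": 5,
    "split": 6,
    "evaluate": 7,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(master_seed), STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def _from_dict(cls, data: dict, path: str):
    """Build a dataclass from a dict, rejecting unknown keys recursively."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        key = sorted(unknown)[0]
        raise ValueError(f"unknown config key {path}{key!r}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        sub = _NESTED.get((cls, name))
        if sub is not None and isinstance(value, dict):
            value = _from_dict(sub, value, f"{path}{name}.")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


@dataclass(frozen=True)
class PathsConfig:
    data_dir: str = "data"
    out_dir: str = "out"
    ucihar_dir: Optional[str] = None
    checkpoint: Optional[str] = None


@dataclass(frozen=True)
class KalmanBlock:
    dt_s: float = 1.0 / 30.0
    q_angle: float = 1e-3
    q_rate: float = 1e-2
    r_angle: float = 4.0
    r_rate: float = 1.0
    p0: float = 1.0


@dataclass(frozen=True)
class PreprocessBlock:
    length: int = 128
    range: Tuple[float, float] = (-1.0, 1.0)
    x_min: float = -180.0
    x_max: float = 180.0


@dataclass(frozen=True)
class ModelBlock:
    kernel_size: int = 10
    filters_per_block: Tuple[int, int] = (16, 16)
    dropout_rate: float = 0.5
    pool_stride: int = 2
    n_classes: int = 6


@dataclass(frozen=True)
class TrainBlock:
    learning_rate: float = 1e-3
    pretrain_learning_rate: float = 1e-2
    epochs: int = 120
    batch_size: int = 32
    split_ratios: Tuple[float, float, float] = (0.6, 0.2, 0.2)


@dataclass(frozen=True)
class FusionBlock:
    rule: str = "nb"
    priors: str = "empirical"  # empirical | uniform
    smoothing: float = 0.0

    def __post_init__(self):
        if self.rule not in ("max", "sum", "ds", "nb"):
            raise ValueError(f"fusion.rule must be max|sum|ds|nb, got {self.rule!r}")
        if self.priors not in ("empirical", "uniform"):
            raise ValueError("fusion.priors must be 'empirical' or 'uniform'")


@dataclass(frozen=True)
class EvaluationBlock:
    alpha: float = 0.05
    repeats: int = 10


@dataclass(frozen=True)
class SimulateBlock:
    n_per_cell: int = 10


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    paths: PathsConfig = field(default_factory=PathsConfig)
    kalman: KalmanBlock = field(default_factory=KalmanBlock)
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    model: ModelBlock = field(default_factory=ModelBlock)
    train: TrainBlock = field(default_factory=TrainBlock)
    fusion: FusionBlock = field(default_factory=FusionBlock)
    evaluation: EvaluationBlock = field(default_factory=EvaluationBlock)
    simulate: SimulateBlock = field(default_factory=SimulateBlock)

    def to_dict(self) -> dict:
        return asdict(self)


_NESTED = {
    (RunConfig, "paths"): PathsConfig,
    (RunConfig, "kalman"): KalmanBlock,
    (RunConfig, "preprocess"): PreprocessBlock,
    (RunConfig, "model"): ModelBlock,
    (RunConfig, "train"): TrainBlock,
    (RunConfig, "fusion"): FusionBlock,
    (RunConfig, "evaluation"): EvaluationBlock,
    (RunConfig, "simulate"): SimulateBlock,
}


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML run config."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return _from_dict(RunConfig, data, "")


def config_hash(config: RunConfig) -> str:
    """Stable hash of the canonical JSON form, for artifact manifests."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
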