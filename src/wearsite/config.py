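"""Pipeline configuration: nested dataclasses, YAML loading, hashing.

A run's effective configuration is fully serializable; unknown keys in a
YAML file are rejected with their key path, and a short SHA-256 hash of the
canonical JSON form is embedded in every artifact the pipeline writes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass

import yaml

from .counts import CountsConfig
from .groundtruth import GroundTruthConfig
from .models import ModelConfig
from .synthdata import CalorimetryConfig, ProtocolConfig, SignalConfig


@dataclass(frozen=True)
class WindowingConfig:
    window_len: int = 100
    stride: int = 100
    trim_s: float = 60.0
    train_fraction: float = 0.9
    split_scheme: str = "window_random"
    # cap on cached windows (seeded subsample); bounds CPU time of the
    # training stages at large cohort sizes.  0 disables the cap.
    max_windows: int = 10_000


@dataclass(frozen=True)
class CohortConfig:
    n_adult: int = 2
    n_child: int = 2
    sites: tuple = ("hip", "wrist", "chest")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    calorimetry: CalorimetryConfig = field(default_factory=CalorimetryConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    groundtruth: GroundTruthConfig = field(default_factory=GroundTruthConfig)
    counts: CountsConfig = field(default_factory=CountsConfig)
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    log_level: str = "INFO"


def _build(cls, data: dict, path: str = ""):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        key = sorted(unknown)[0]
        raise ValueError(f"unknown config key: {path}{key}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        default = known[name].default_factory() \
            if known[name].default_factory is not dataclasses.MISSING \
            else known[name].default
        if is_dataclass(default) and isinstance(value, dict):
            kwargs[name] = _build(type(default), value, f"{path}{name}.")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config (or defaults), applying top-level overrides."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
    if overrides:
        data = {**data, **{k: v for k, v in overrides.items() if v is not None}}
    return _build(PipelineConfig, data)


def _to_jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name))
                for f in fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def config_to_dict(config: PipelineConfig) -> dict:
    return _to_jsonable(config)


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash of the canonical JSON form."""
    blob = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
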