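"""Pipeline configuration: YAML schema, validation and hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .exceptions import SchemaError

__all__ = ["Thresholds", "PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class Thresholds:
    """All analysis cutoffs; defaults are the published values."""

    alpha_nominal: float = 0.05
    alpha_combined: float = 0.01
    min_per_group: int = 3
    min_gq: int = 15
    min_depth: int = 8
    min_mq: float = 20.0
    min_qd: float = 2.0
    max_fs: float = 50.0
    se_min_length: int = 3000
    window: int = 50

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v <= 0:
                raise SchemaError(f"threshold {name} must be positive, got {v}")
        if not (self.alpha_nominal < 1 and self.alpha_combined < 1):
            raise SchemaError("alpha thresholds must be < 1")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "aisle_out"
    thresholds: Thresholds = field(default_factory=Thresholds)
    stage_order: tuple[str, ...] = ("rN", "T3", "SM", "DN")
    simulate: dict[str, Any] = field(default_factory=dict)
    discovery: dict[str, Any] = field(default_factory=dict)
    annotation: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.stage_order) < 2:
            raise SchemaError("stage_order needs >=2 entries")

    def hash(self) -> str:
        return config_hash(self)


_KNOWN_KEYS = {"seed", "out_dir", "thresholds", "stage_order", "simulate", "discovery", "annotation"}


def load_config(path: str | Path | Mapping[str, Any]) -> PipelineConfig:
    """Load and validate a pipeline config from YAML (or a mapping)."""
    if isinstance(path, Mapping):
        raw = dict(path)
    else:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    th = Thresholds(**raw.get("thresholds", {}))
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "aisle_out")),
        thresholds=th,
        stage_order=tuple(raw.get("stage_order", ("rN", "T3", "SM", "DN"))),
        simulate=dict(raw.get("simulate", {})),
        discovery=dict(raw.get("discovery", {})),
        annotation=dict(raw.get("annotation", {})),
    )


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the full configuration (stamped on outputs)."""
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
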