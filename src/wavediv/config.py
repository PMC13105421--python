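"""Pipeline configuration: every tunable in one place, YAML round-trippable."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Tuple

import yaml

from .exceptions import ValidationError


@dataclass(frozen=True)
class PipelineConfig:
    wavelet_name: str = "db4"
    levels: int = 4
    patch_side: int = 256
    n_bins: int = 64
    bandwidth: float = 1.0  # smoothing sd, in bins
    entropy_bins: int = 64
    jsd_variant: str = "standard"  # or "printed" (archaeological)
    consensus_policy: str = "median"
    band_edges: Tuple[float, float] = (0.4, 0.6)
    calibration_anchors: Tuple[float, float, float] = (0.2, 0.5, 0.8)
    bootstrap_n: int = 10000
    split_by: str = "source"  # "source" (leakage-safe) or "patch"

    def __post_init__(self) -> None:
        e1, e2 = self.band_edges
        if not (0.0 < e1 < e2 < 1.0):
            raise ValidationError("band_edges must be strictly increasing in (0,1)")
        a = self.calibration_anchors
        if not (0.0 < a[0] < a[1] < a[2] < 1.0):
            raise ValidationError(
                "calibration_anchors must be strictly increasing in (0,1)"
            )
        if self.jsd_variant not in ("standard", "printed"):
            raise ValidationError(f"unknown jsd_variant {self.jsd_variant!r}")
        if self.split_by not in ("source", "patch"):
            raise ValidationError(f"unknown split_by {self.split_by!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("band_edges", "calibration_anchors"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)
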