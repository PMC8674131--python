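"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Knobs for a full pipeline run.

    ``iterations`` is the resampling count for the null distribution;
    ``ridge`` regularises the between-subject covariance; ``quantile``
    is the "within the reference distribution" cut-off; ``window_mm``
    the square depth-sampling window around each landmark.
    """

    seed: int = 0
    iterations: int = 1000
    ridge: float = 1e-8
    quantile: float = 0.95
    window_mm: float = 10.0
    toe_depth_convention: str = "log_ratio"
    stature_slope: float | None = None  # cm per mm; user-supplied
    stature_intercept: float | None = None  # cm
    midline: str = "ols"
    # synthetic-population sizes (simulate stage)
    n_reference_subjects: int = 40
    n_reference_tracks: int = 6
    n_outgroup_subjects: int = 2
    n_outgroup_tracks: int = 20

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not 0 < self.quantile <= 1:
            raise ValueError("quantile must be in (0, 1]")
        if self.window_mm <= 0:
            raise ValueError("window_mm must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance blocks."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
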