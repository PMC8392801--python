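"""Run configuration: the fixed analysis constants, YAML loading, provenance.

Every output file embeds the package version and a SHA-256 hash of the fully
resolved configuration so that runs are auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All tunable analysis parameters with their documented defaults."""

    threshold_fraction: float = 0.41      # lesion segmentation: fraction of SUVmax
    connectivity: int = 26                # voxel adjacency: 6, 18 or 26
    centroid_weighting: str = "geometric"  # 'geometric' | 'suv'
    tsp_mode: str = "heuristic"           # 'heuristic' | 'exact'
    tsp_metric: str = "euclidean"
    cutoff_method: str = "maxstat"        # 'maxstat' | 'youden'
    ties: str = "efron"                   # Cox tie handling: 'efron' | 'breslow'
    mtv_threshold_ml: float = 220.0       # high-tumor-burden dichotomy, cm3
    ecog_threshold: int = 2               # poor performance status: ECOG >= 2
    horizon_months: float = 48.0          # fixed-horizon ROC outcome option
    n_permutations: int = 0               # maxstat permutation correction (0 = off)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.centroid_weighting not in ("geometric", "suv"):
            raise ValueError("centroid_weighting must be 'geometric' or 'suv'")
        if self.tsp_mode not in ("heuristic", "exact"):
            raise ValueError("tsp_mode must be 'heuristic' or 'exact'")
        if self.cutoff_method not in ("maxstat", "youden"):
            raise ValueError("cutoff_method must be 'maxstat' or 'youden'")
        if self.ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        if self.mtv_threshold_ml <= 0 or self.horizon_months <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML; missing keys take the defaults above."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def digest(self) -> str:
        """SHA-256 of the canonical JSON form (first 12 hex chars)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
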