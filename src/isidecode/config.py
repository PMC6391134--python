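"""Run configuration with the method's published defaults.

A bare configuration reproduces the standard analysis settings: 1 s
likelihood windows recalculated every 100 ms, 750 ms consensus windows,
10-fold cross-validation repeated 124 times, and 1240 null repetitions.
YAML and JSON serializations are equivalent and round-trip exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    window_length_s: float = 1.0
    window_step_s: float = 0.1
    consensus_window_s: float = 0.75
    consensus_step_s: float = 0.1
    folds: int = 10
    reps: int = 124
    null_reps: int = 1240
    cv_folds: int = 10
    grid_points: int = 512
    isi_min_s: float = 1e-3
    isi_max_s: float = 10.0
    density_floor: float = 1e-9
    pre_trial_bound_s: float = 0.3
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        for name in ("window_length_s", "window_step_s", "consensus_window_s",
                     "consensus_step_s", "isi_min_s", "isi_max_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("folds", "reps", "null_reps", "cv_folds", "grid_points"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
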