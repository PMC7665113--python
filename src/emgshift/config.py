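"""Pipeline configuration.

All defaults are the operating point of the recognition pipeline: 200
sample (1 s) windows, 7 training windows per repetition at stride 25,
test stride 20, an energy gate at 17% of the calibrated group-mean
energy, score-validation threshold 0.9, overlap threshold 0.25 and up
to 4 synchronization repetitions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import yaml


@dataclass
class PipelineConfig:
    window_len: int = 200
    train_stride: int = 25
    test_stride: int = 20
    windows_per_rep: int = 7
    energy_fraction: float = 0.17
    ps_threshold: float = 0.9
    rho_threshold: float = 0.25
    sync_count: int = 4
    reps_per_gesture: int = 25
    mode_block: int = 4
    seed: int = 0
    # resolution of genuinely open procedural choices; defaults documented
    # in docs/methods.md
    group_energy: Literal["mean", "sum"] = "mean"
    ae_reduce: Literal["mean", "max"] = "mean"
    mode_stride: Literal["sliding", "block"] = "sliding"

    def __post_init__(self) -> None:
        for name in ("energy_fraction", "ps_threshold", "rho_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 1 <= self.sync_count <= 4:
            raise ValueError(f"sync_count must be in [1, 4], got {self.sync_count}")
        if self.window_len <= max(self.train_stride, self.test_stride):
            raise ValueError("window_len must exceed both strides")
        if self.mode_block < 1 or self.windows_per_rep < 1 or self.reps_per_gesture < 1:
            raise ValueError("counts must be positive")
        if self.group_energy not in ("mean", "sum"):
            raise ValueError(f"group_energy must be 'mean' or 'sum', got {self.group_energy}")
        if self.ae_reduce not in ("mean", "max"):
            raise ValueError(f"ae_reduce must be 'mean' or 'max', got {self.ae_reduce}")
        if self.mode_stride not in ("sliding", "block"):
            raise ValueError(f"mode_stride must be 'sliding' or 'block', got {self.mode_stride}")

    # -- persistence --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)
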