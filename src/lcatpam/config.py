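"""Run configuration shared by the CLI subcommands.

Defaults encode the study protocol: residue pair 50/65, the last-half
analysis window, ten blocks for block averaging, nm distance reporting, the
100–600 g/mol mass window with the −7.0 SP-score cut-off, and α = 0.05.
A bare command therefore reproduces the protocol without flags.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    residue_a: int = 50
    residue_b: int = 65
    window: str | tuple[float, float] = "last_half"  # or (t_start, t_end) in ns
    n_blocks: int = 10
    distance_unit: str = "nm"
    mass_min: float = 100.0
    mass_max: float = 600.0
    score_cutoff: float = -7.0
    alpha: float = 0.05
    activator_threshold_pct: float = 100.0
    prediction_level: float = 0.95
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.distance_unit not in ("nm", "angstrom"):
            raise ValueError(f"unknown distance_unit {self.distance_unit!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.mass_min >= self.mass_max:
            raise ValueError("mass_min must be < mass_max")
        if isinstance(self.window, list):
            self.window = tuple(self.window)
        if not (self.window == "last_half" or (
            isinstance(self.window, tuple) and len(self.window) == 2
        )):
            raise ValueError("window must be 'last_half' or (t_start, t_end)")

    def window_tuple(self) -> tuple[float, float] | None:
        return None if self.window == "last_half" else tuple(self.window)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
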