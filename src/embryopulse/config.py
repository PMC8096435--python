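"""Run configuration: every method constant in one place.

The defaults are the values used throughout the analyses (PIV window
sizes, the 50–120 s oscillation band and 1.7× threshold, the 7 h growth
window and 35 % growth filter, the 30-min wave rule, the 20 µm lumen
criterion); nothing is hard-coded elsewhere.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    presets: list[str] = field(default_factory=lambda: ["WT", "mzMyh9"])
    seed: int = 0
    output_dir: str = "results"
    # cohort sizes per genotype
    n_angle: int = 10
    n_timeline: int = 10
    n_area: int = 10
    n_movies: int = 2
    # movie calibration overrides
    pixel_size_um: float = 0.5
    frame_interval_s: float = 5.0
    movie_n_frames: int = 120
    # PIV
    window_pass1_um: float = 20.0
    window_pass2_um: float = 10.0
    overlap: float = 0.54
    # oscillation call
    band_low_s: float = 50.0
    band_high_s: float = 120.0
    oscillation_threshold: float = 1.7
    # morphometrics
    growth_window_h: float = 7.0
    min_growth_fraction: float = 0.35
    # events
    wave_gap_min: float = 30.0
    lumen_diameter_um: float = 20.0

    def __post_init__(self) -> None:
        if self.band_low_s >= self.band_high_s:
            raise ValueError("band low must be below band high")
        positives = (
            self.pixel_size_um, self.frame_interval_s, self.window_pass1_um,
            self.window_pass2_um, self.oscillation_threshold,
            self.growth_window_h, self.wave_gap_min, self.lumen_diameter_um,
        )
        if any(p <= 0 for p in positives):
            raise ValueError("all physical thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash tying every output CSV to this exact configuration."""
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
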