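"""Run configuration: one structured file holding every analysis parameter.

Defaults reproduce the assay's stated settings (64 → 32 px PIV passes, 2 s
kinetics window, 2× BTX threshold, ±50 µm perinuclear bands, ROUT Q = 1).
The config round-trips losslessly through YAML, and its SHA-1 hash is
embedded in every output CSV so results are traceable to their parameters.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # calibration
    pixel_size: float = 0.25  # µm/px
    frame_interval: float = 0.02  # s
    # PIV
    pass_windows: tuple[int, ...] = (64, 32)
    overlap_fraction: float = 0.5
    validation_threshold: float = 2.0
    validation_eps: float = 0.1
    # kinetics
    kinetics_window: float = 2.0  # s
    prominence_fraction: float = 0.1
    fft_pad_factor: int = 4
    noise_floor_factor: float = 5.0
    baseline_window: float | None = None  # s; enables the fatigue readout
    stop_threshold_factor: float = 2.0
    fatigue_sustain: float = 1.0  # s
    # morphometry
    background_radius: float = 50.0  # px, rolling-ball
    mask_min_area: int = 64  # px
    nucleus_min_area: int = 9  # px
    min_overlap: float = 0.5
    # scoring
    btx_factor: float = 2.0
    histogram_bins: int = 64
    perinuclear_half_length: float = 50.0  # µm
    spot_min_area: int = 1  # px
    spot_max_area: int | None = None
    # stats
    rout_q: float = 1.0  # percent
    # misc
    seed: int = 0
    output_dir: str = "twitchkit_out"

    def piv_config(self):
        from .piv import PivConfig

        return PivConfig(
            pass_windows=tuple(self.pass_windows),
            overlap_fraction=self.overlap_fraction,
            validation_threshold=self.validation_threshold,
            validation_eps=self.validation_eps,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pass_windows"] = list(d["pass_windows"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "pass_windows" in d:
            d["pass_windows"] = tuple(d["pass_windows"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]
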