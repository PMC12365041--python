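"""Pipeline configuration: every tunable constant in one place.

Defaults are the canonical analysis values: 4-s epochs; slow/delta/sigma
band edges 0.5-1.0 / 1.0-4.5 / 10.0-15.0 Hz; infraslow FIR lowpass at
0.025 Hz with 100 taps; cross-correlation and PSD segments from NREMS
runs > 300 s with the first 100 s deleted (PSD cut to 200 s);
peak-to-peak segments from runs >= 150 s trimmed 16 s / 4 s; MA rule
12 / 16 / 4 s; stimulation trains of 50 s at 10 Hz with a 50-s minimum
gap.  Configs load from YAML or JSON mappings and hash stably so outputs
can be traced to the exact configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SegmentRecipe", "PipelineConfig"]


@dataclass(frozen=True)
class SegmentRecipe:
    """Consolidated-NREMS segment selection parameters (seconds)."""

    min_len: float
    trim_start: float = 0.0
    trim_end: float = 0.0
    cut_to: float | None = None
    min_len_inclusive: bool = False

    def kwargs(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class PipelineConfig:
    epoch_length: float = 4.0
    band_edges: dict = field(
        default_factory=lambda: {
            "slow": (0.5, 1.0), "delta": (1.0, 4.5), "sigma": (10.0, 15.0)
        }
    )
    filter_cutoff: float = 0.025  # Hz
    filter_taps: int = 100
    xcorr_segments: SegmentRecipe = field(
        default_factory=lambda: SegmentRecipe(min_len=300.0, trim_start=100.0, cut_to=200.0)
    )
    psd_segments: SegmentRecipe = field(
        default_factory=lambda: SegmentRecipe(min_len=300.0, trim_start=100.0, cut_to=200.0)
    )
    p2p_segments: SegmentRecipe = field(
        default_factory=lambda: SegmentRecipe(
            min_len=150.0, trim_start=16.0, trim_end=4.0, min_len_inclusive=True
        )
    )
    ma_max_s: float = 12.0
    ma_pre_s: float = 16.0
    ma_post_s: float = 4.0
    min_bout_s: float = 4.0
    state_mean_min_bout_s: float = 16.0
    transition_min_epochs: int = 5
    p2p_min_separation: float = 40.0
    zscore_scope: str = "all_nrem"
    train_duration: float = 50.0
    min_gap: float = 50.0
    pulse_rate: float = 10.0
    seed: int = 0
    output_dir: str = "somnarc_out"

    def __post_init__(self) -> None:
        el = self.epoch_length
        for name in ("ma_max_s", "ma_pre_s", "ma_post_s", "min_bout_s",
                     "state_mean_min_bout_s"):
            v = getattr(self, name)
            if abs(v / el - round(v / el)) > 1e-9:
                raise ValueError(f"{name}={v} is not a multiple of epoch_length={el}")
        for band, (lo, hi) in self.band_edges.items():
            if not lo < hi:
                raise ValueError(f"band {band}: edges must be ordered, got ({lo}, {hi})")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("xcorr_segments", "psd_segments", "p2p_segments"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = SegmentRecipe(**kwargs[key])
        if "band_edges" in kwargs:
            kwargs["band_edges"] = {k: tuple(v) for k, v in kwargs["band_edges"].items()}
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
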