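"""Relative EEG band powers and the pre-REMS sigma surge.

Band powers are exported per 4-s epoch for the slow (0.5-1.0 Hz), delta
(1.0-4.5 Hz) and sigma (10.0-15.0 Hz) bands plus the full spectrum.
Relative power expresses each epoch as a percentage of the mean
full-band power over the recording, making the measures invariant to
global gain.  State means are two-level averages (per bout, then per
state) over MA-merged bouts of at least 16 s.

At NREMS->REMS transitions, sigma power transiently surges in the final
tens of seconds of NREMS.  :func:`sigma_surge` reproduces the transition
analysis: infraslow-lowpass the relative sigma trace, average windows
aligned at the first REMS epoch, upsample the average to 10 Hz (PCHIP)
and locate the highest peak within the last 50 s of NREMS; the latency
is the time from that peak to REMS entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .hypnogram import Hypnogram, detect_bouts
from .infraslow import lowpass_infraslow

BANDS = ("slow", "delta", "sigma", "full")

#: Band edges in Hz, as exported by the acquisition software.
BAND_EDGES = {"slow": (0.5, 1.0), "delta": (1.0, 4.5), "sigma": (10.0, 15.0)}

__all__ = [
    "EpochPowerSeries",
    "SurgeResult",
    "relative_band_power",
    "state_mean_power",
    "sigma_surge",
]


@dataclass(frozen=True)
class EpochPowerSeries:
    """Per-epoch band power densities aligned 1:1 with a hypnogram."""

    time: np.ndarray
    powers: pd.DataFrame  # columns = BANDS

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        missing = [b for b in BANDS if b not in self.powers.columns]
        if missing:
            raise ValueError(f"missing band columns: {missing}")
        if len(self.powers) != t.size:
            raise ValueError("time and powers length mismatch")
        if (self.powers[list(BANDS)].to_numpy() < 0).any():
            raise ValueError("band powers must be non-negative")
        object.__setattr__(self, "time", t)

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class SurgeResult:
    """Pre-REMS sigma surge: averaged transition trace, peak and latency."""

    peak_amplitude: float  # % relative power at the peak
    latency_to_rems: float  # seconds from peak to the first REMS epoch
    n_transitions: int
    trace_time: np.ndarray  # seconds relative to REMS entry, 10-Hz grid
    mean_transition_trace: np.ndarray


def relative_band_power(powers: EpochPowerSeries) -> pd.DataFrame:
    """Express each band as % of the recording's mean full-band power.

    ``rel[band][i] = 100 * band[i] / mean(full)``, so the relative
    full-band power averages to exactly 100% and all relative measures
    are invariant to a global rescaling of the raw powers.
    """
    denom = float(powers.powers["full"].mean())
    if denom <= 0:
        raise ValueError("mean full-band power must be positive")
    rel = powers.powers[list(BANDS)] * (100.0 / denom)
    rel.index = pd.RangeIndex(len(rel))
    return rel


def state_mean_power(
    rel: pd.DataFrame,
    hyp: Hypnogram,
    min_bout: float = 16.0,
    include_ma_epochs: bool = True,
) -> pd.DataFrame:
    """Two-level state averages of relative power (per bout, then per state).

    Epochs are grouped into MA-merged bouts of at least ``min_bout``
    seconds; each bout contributes its mean relative power, and the state
    mean is the unweighted mean of its bout means (bout-weighted, not
    epoch-weighted).  MA epochs inside merged NREMS bouts are included
    unless ``include_ma_epochs=False``.  States without a qualifying bout
    are absent from the result (missing, not zero).
    """
    if len(rel) != len(hyp):
        raise ValueError("relative powers and hypnogram length mismatch")
    bouts = detect_bouts(hyp, min_duration=min_bout, merge_ma=True)
    rows = {}
    arr = rel.to_numpy()
    scores = hyp.scores
    for state, grp in bouts.groupby("state"):
        means = []
        for _, b in grp.iterrows():
            sl = np.arange(int(b["start"]), int(b["end"]))
            if state == "N" and not include_ma_epochs:
                sl = sl[scores[sl] != "M"]
            if sl.size:
                means.append(arr[sl].mean(axis=0))
        if means:
            rows[state] = np.mean(means, axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(rel.columns))


def sigma_surge(
    rel_sigma: np.ndarray,
    hyp: Hypnogram,
    transitions: list[int],
    fs: float = 0.25,
    window: tuple[float, float] = (-200.0, 60.0),
    search_span: float = 50.0,
    upsample_rate: float = 10.0,
    prefiltered: bool = False,
    interpolation: str = "pchip",
) -> SurgeResult:
    """Locate the sigma surge preceding REMS entries.

    ``rel_sigma`` is the per-epoch relative sigma power over the full
    recording; ``transitions`` the first-REMS epoch indices from
    :func:`somnarc.hypnogram.detect_transitions`.  The trace is infraslow
    lowpass-filtered (unless ``prefiltered``), windows spanning
    ``window`` seconds around each REMS entry are averaged pointwise
    (transitions missing data at a given offset are excluded there, not
    padded), the average is upsampled to ``upsample_rate`` Hz and the
    highest peak within the final ``search_span`` seconds of NREMS is
    reported with its latency to REMS entry.
    """
    x = np.asarray(rel_sigma, dtype=float)
    if len(x) != len(hyp):
        raise ValueError("rel_sigma and hypnogram length mismatch")
    if not transitions:
        warnings.warn("no NREMS->REMS transitions; empty surge result")
        return SurgeResult(float("nan"), float("nan"), 0, np.array([]), np.array([]))
    if not prefiltered:
        x = lowpass_infraslow(x, fs=fs)
    el = hyp.epoch_length
    k_pre = int(round(-window[0] / el))
    k_post = int(round(window[1] / el))
    stack = np.full((len(transitions), k_pre + k_post), np.nan)
    for j, t in enumerate(transitions):
        lo, hi = t - k_pre, t + k_post
        src_lo, src_hi = max(lo, 0), min(hi, len(x))
        stack[j, src_lo - lo:src_hi - lo] = x[src_lo:src_hi]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns at edges
        mean_trace = np.nanmean(stack, axis=0)
    # epoch power represents [t, t + epoch_length): attribute it to the midpoint
    offsets = (np.arange(-k_pre, k_post) + 0.5) * el
    valid = ~np.isnan(mean_trace)
    offsets, mean_trace = offsets[valid], mean_trace[valid]
    step = 1.0 / upsample_rate
    grid = np.arange(offsets[0], offsets[-1] + step / 2, step)
    if interpolation == "pchip":
        fine = PchipInterpolator(offsets, mean_trace)(grid)
    elif interpolation == "linear":
        fine = np.interp(grid, offsets, mean_trace)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    search = (grid >= -search_span) & (grid <= 0.0)
    si = np.flatnonzero(search)
    peaks, _ = sps.find_peaks(fine[si])
    if peaks.size == 0:
        warnings.warn("no sigma peak within the pre-REMS search window")
        return SurgeResult(float("nan"), float("nan"), len(transitions), grid, fine)
    best = si[peaks[np.argmax(fine[si][peaks])]]
    peak_time = float(grid[best])
    return SurgeResult(
        peak_amplitude=float(fine[best]),
        latency_to_rems=-peak_time,
        n_transitions=len(transitions),
        trace_time=grid,
        mean_transition_trace=fine,
    )
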