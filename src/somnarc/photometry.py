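"""Fiber-photometry preprocessing: downsampling, envelope, bleaching
correction and NREMS-referenced z-scoring.

The raw fluorescence trace (GRAB-sensor output, arbitrary units) is
brought onto the EEG epoch grid (0.25 Hz for 4-s epochs) by linear
interpolation, optionally upsampled to a 1-s display envelope with a
monotone piecewise-cubic (PCHIP) interpolant, corrected for photobleaching
by dividing out a degree-2 polynomial fitted by least squares to the
NREMS samples only, and standardized against the NREMS mean and SD:

    dF/F = (F - fit) / fit
    z    = (dF/F - mean(dF/F | NREMS)) / SD(dF/F | NREMS)

Because the baseline is fitted on NREMS, dF/F is multiplicative-scale
invariant (F -> cF leaves it unchanged) and the wake/REMS artifact drops
common to GRAB sensors do not bias the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .hypnogram import Hypnogram, detect_bouts

__all__ = [
    "PhotometryTrace",
    "SampledSeries",
    "DffSeries",
    "downsample_to_epoch_rate",
    "envelope_1s",
    "bleach_correct",
    "zscore_nrem",
]


@dataclass(frozen=True)
class PhotometryTrace:
    """Raw fluorescence trace with timestamps (seconds, strictly increasing)."""

    time: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.F, dtype=float)
        if t.size != f.size or t.size < 2:
            raise ValueError("trace needs >= 2 (time, F) samples of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("photometry time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "F", f)

    @property
    def sampling_rate(self) -> float:
        return float((self.time.size - 1) / (self.time[-1] - self.time[0]))


@dataclass(frozen=True)
class SampledSeries:
    """Uniformly sampled series (time in seconds, rate in Hz)."""

    time: np.ndarray
    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class DffSeries:
    """dF/F on the epoch-rate grid with its NREMS mask and bleaching fit.

    ``fit_coeffs`` are the degree-2 polynomial coefficients in
    ``numpy.polyfit`` order (highest degree first).
    """

    time: np.ndarray
    dff: np.ndarray
    nrem_mask: np.ndarray
    fit_coeffs: np.ndarray
    z: np.ndarray | None = None
    rate: float = 0.25


def downsample_to_epoch_rate(
    trace: PhotometryTrace,
    target_rate: float = 0.25,
    start_time: float | None = None,
    pre_average: bool = False,
) -> SampledSeries:
    """Resample a trace onto the epoch grid by linear interpolation.

    The grid runs at ``target_rate`` from ``start_time`` (default: the
    first multiple of the grid step at or after the trace start) and must
    lie entirely inside the trace's time span.  ``pre_average`` applies a
    one-grid-step moving average before interpolation for robustness to
    broadband noise; the plain variant matches 1-D linear interpolation
    with no anti-alias filtering.
    """
    if trace.sampling_rate < target_rate:
        raise ValueError("trace sampling rate below the target rate")
    step = 1.0 / target_rate
    t0, t1 = trace.time[0], trace.time[-1]
    if start_time is None:
        start_time = np.ceil(t0 / step) * step
    if start_time < t0 - 1e-9:
        raise ValueError("requested grid starts before the trace")
    n = int(np.floor((t1 - start_time) / step + 1e-9)) + 1
    if n < 1:
        raise ValueError("requested grid lies outside the trace time span")
    grid = start_time + np.arange(n) * step
    f = trace.F
    if pre_average:
        w = max(1, int(round(step * trace.sampling_rate)))
        kernel = np.ones(w) / w
        f = np.convolve(f, kernel, mode="same")
    values = np.interp(grid, trace.time, f)
    return SampledSeries(grid, values, target_rate)


def envelope_1s(series: SampledSeries, target_rate: float = 1.0) -> SampledSeries:
    """Monotone piecewise-cubic (PCHIP) upsampling to a 1-s grid.

    Shape preserving: the interpolant never overshoots local extrema of
    the input and reproduces the input exactly at the original grid
    points.  Intended for display and peak alignment; the analyses
    operate on the epoch-rate series.
    """
    if series.values.size < 2:
        raise ValueError("need at least 2 samples to build an envelope")
    interp = PchipInterpolator(series.time, series.values)
    step = 1.0 / target_rate
    n = int(np.floor((series.time[-1] - series.time[0]) / step + 1e-9)) + 1
    grid = series.time[0] + np.arange(n) * step
    return SampledSeries(grid, interp(grid), target_rate)


def _nrem_mask(series: SampledSeries, hyp: Hypnogram) -> np.ndarray:
    """Boolean mask of samples falling in strict-NREMS epochs (MA excluded)."""
    idx = np.floor((series.time - hyp.start_time) / hyp.epoch_length + 1e-9).astype(int)
    if idx.min() < 0 or idx.max() >= len(hyp):
        raise ValueError("series extends beyond the hypnogram")
    return hyp.scores[idx] == "N"


def bleach_correct(series: SampledSeries, hyp: Hypnogram) -> DffSeries:
    """Divide out a NREMS-fitted degree-2 bleaching polynomial.

    The polynomial is fitted by ordinary least squares to the (time, F)
    pairs of NREMS samples only (MA epochs excluded), evaluated over the
    whole recording, and dF/F computed as ``(F - fit) / fit``.  Raises if
    fewer than 3 NREMS samples are available or the fitted baseline is
    not strictly positive everywhere.
    """
    mask = _nrem_mask(series, hyp)
    if mask.sum() < 3:
        raise ValueError("need >= 3 NREMS samples for the degree-2 bleaching fit")
    coeffs = np.polyfit(series.time[mask], series.values[mask], 2)
    fit = np.polyval(coeffs, series.time)
    bad = fit <= 0
    if bad.any():
        t_bad = series.time[np.flatnonzero(bad)[0]]
        raise ValueError(f"bleaching fit is non-positive at t={t_bad:.1f} s")
    dff = (series.values - fit) / fit
    return DffSeries(series.time, dff, mask, coeffs, rate=series.rate)


def split_sections(dff: DffSeries, hyp: Hypnogram, max_wake_gap: float = 60.0) -> list[np.ndarray]:
    """Index arrays of signal sections separated by wake runs > ``max_wake_gap``."""
    wake_bouts = detect_bouts(hyp, state="W", min_duration=0.0, merge_ma=False)
    long_wake = wake_bouts[wake_bouts["duration_s"] > max_wake_gap]
    cut_epochs = sorted(set(long_wake["start"]).union(long_wake["end"]))
    idx = np.floor((dff.time - hyp.start_time) / hyp.epoch_length + 1e-9).astype(int)
    bounds = [0] + [int(np.searchsorted(idx, c)) for c in cut_epochs] + [dff.time.size]
    sections = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a:
            sections.append(np.arange(a, b))
    return sections


def zscore_nrem(
    dff: DffSeries,
    hyp: Hypnogram | None = None,
    scope: str = "all_nrem",
) -> DffSeries:
    """Standardize dF/F against its NREMS mean and SD.

    ``scope="all_nrem"`` uses one mean/SD over every NREMS sample;
    ``scope="per_section"`` splits the recording at wake runs longer than
    60 s (requires the hypnogram) and standardizes each section against
    its own NREMS statistics.  SD is the population SD (ddof=0).  Every
    sample in a scope is transformed, not only the NREMS ones.
    """
    mask = dff.nrem_mask
    if not mask.any():
        raise ValueError("empty NREMS mask; nothing to standardize against")
    z = np.full_like(dff.dff, np.nan)
    if scope == "all_nrem":
        sections = [np.arange(dff.dff.size)]
    elif scope == "per_section":
        if hyp is None:
            raise ValueError('scope="per_section" needs the hypnogram')
        sections = split_sections(dff, hyp)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    for sec in sections:
        m = mask[sec]
        if not m.any():
            continue
        ref = dff.dff[sec][m]
        sd = float(ref.std(ddof=0))
        if sd == 0:
            raise ValueError(
                "zero dF/F SD over NREMS in one scope; the signal is constant "
                "there and cannot be z-scored"
            )
        z[sec] = (dff.dff[sec] - float(ref.mean())) / sd
    return replace(dff, z=z)
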