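"""Infraslow-band analysis of NREMS signals.

During consolidated NREMS, sigma power (10-15 Hz) is modulated by an
infraslow oscillation (ISO) of ~0.02 Hz (~50-s period); CRH release in
the thalamic reticular nucleus oscillates on the same timescale in
anti-phase.  This module isolates the infraslow band with a zero-phase
FIR lowpass (0.025 Hz, 100 taps), cross-correlates paired signals over
consolidated NREMS segments, measures peak-to-peak amplitudes, and
estimates infraslow power spectral densities from 200-s NREMS bouts with
one-segment Welch periodograms (Hann window) normalized to unit area.

All operations assume the 0.25-Hz epoch-rate grid.  Filtering is applied
to the full recording before segment extraction: the zero-phase padding
(3 x taps) could not be honoured on 50-75-sample bouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "CrossCorrResult",
    "PsdResult",
    "lowpass_infraslow",
    "crosscorrelate_segments",
    "peak_to_peak",
    "psd_infraslow",
    "sigma_psd_baseline",
]


@dataclass(frozen=True)
class CrossCorrResult:
    """Segment-averaged cross-correlation of two NREMS signals.

    ``lags`` are in seconds, symmetric about 0; a positive lag means the
    first signal (x, e.g. CRH) follows the second (y, e.g. sigma).
    ``r_lag0`` equals the mean Pearson r at zero lag; ``r_max`` is the
    signed value of largest magnitude within the search window around
    zero lag and ``lag_at_max`` its lag.
    """

    lags: np.ndarray
    mean_corr: np.ndarray
    r_lag0: float
    r_max: float
    lag_at_max: float
    n_segments: int


@dataclass(frozen=True)
class PsdResult:
    """Infraslow power spectral density averaged over NREMS bouts."""

    freqs: np.ndarray
    density: np.ndarray
    segment_length: float
    n_segments: int
    normalized: bool = True
    baseline_corrected: bool = False


def design_lowpass(cutoff: float = 0.025, taps: int = 100, fs: float = 0.25) -> np.ndarray:
    """Hamming-windowed-sinc FIR lowpass coefficients with unit DC gain."""
    return sps.firwin(taps, cutoff, window="hamming", fs=fs)


def lowpass_infraslow(
    values: np.ndarray,
    fs: float = 0.25,
    cutoff: float = 0.025,
    taps: int = 100,
) -> np.ndarray:
    """Zero-phase FIR lowpass isolating the infraslow band.

    Applied forward-backward (``filtfilt``) with odd-reflection padding
    of length ``3*taps``, so the output has no phase shift and the
    effective amplitude response is the squared FIR response.  Requires
    the full-recording series: length must exceed ``3*taps`` samples.
    """
    x = np.asarray(values, dtype=float)
    padlen = 3 * taps
    if x.size <= padlen:
        raise ValueError(
            f"series too short for zero-phase filtering: need > {padlen} samples "
            f"({padlen / fs:.0f} s at {fs} Hz), got {x.size}"
        )
    b = design_lowpass(cutoff, taps, fs)
    return sps.filtfilt(b, [1.0], x, padtype="odd", padlen=padlen)


def _unit_norm(seg: np.ndarray) -> np.ndarray:
    """Center and scale to unit Euclidean norm (zero vectors pass through)."""
    c = seg - seg.mean()
    nrm = np.linalg.norm(c)
    return c / nrm if nrm > 0 else c


def crosscorrelate_segments(
    x: np.ndarray,
    y: np.ndarray,
    segments: list[tuple[int, int]],
    fs: float = 0.25,
    max_lag: float = 100.0,
) -> CrossCorrResult:
    """Segment-averaged full cross-correlation of two aligned signals.

    Per segment both channels are centered and scaled to unit Euclidean
    norm, so the zero-lag value is the Pearson correlation coefficient.
    The full cross-correlations are aligned at lag 0 and averaged across
    segments (all segments must be of equal length).  ``r_max`` is the
    signed extremum of largest magnitude within ``max_lag`` seconds of
    zero lag; ties resolve to the lag nearest zero.

    Sign convention: positive lag means x follows (lags behind) y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must share the grid")
    if not segments:
        warnings.warn("no segments supplied; empty cross-correlation result")
        return CrossCorrResult(np.array([]), np.array([]), np.nan, np.nan, np.nan, 0)
    lengths = {e - s for s, e in segments}
    if len(lengths) != 1:
        raise ValueError(f"segments of unequal length: {sorted(lengths)}")
    L = lengths.pop()
    if L < 2:
        raise ValueError("segments must contain at least 2 samples")
    curves = []
    for s, e in segments:
        xs = _unit_norm(x[s:e])
        ys = _unit_norm(y[s:e])
        curves.append(sps.correlate(xs, ys, mode="full"))
    mean_corr = np.mean(curves, axis=0)
    lags = sps.correlation_lags(L, L, mode="full") / fs
    i0 = int(np.flatnonzero(lags == 0)[0])
    r_lag0 = float(mean_corr[i0])
    window = np.abs(lags) <= max_lag
    wi = np.flatnonzero(window)
    order = np.lexsort((np.abs(lags[wi]), -np.abs(mean_corr[wi])))
    best = wi[order[0]]
    return CrossCorrResult(
        lags=lags,
        mean_corr=mean_corr,
        r_lag0=r_lag0,
        r_max=float(mean_corr[best]),
        lag_at_max=float(lags[best]),
        n_segments=len(segments),
    )


def peak_to_peak(
    values: np.ndarray,
    segments: list[tuple[int, int]],
    fs: float = 0.25,
    min_separation: float = 40.0,
) -> float:
    """Mean absolute difference between adjacent peaks and valleys.

    Peaks and valleys are detected independently within each segment
    with a minimum distance of ``min_separation`` seconds between
    same-kind extrema, interleaved by time, and every adjacent
    opposite-kind pair contributes its absolute amplitude difference.
    Returns NaN (missing) when no peak-valley pair exists anywhere.
    """
    x = np.asarray(values, dtype=float)
    dist = max(1, int(round(min_separation * fs)))
    diffs: list[float] = []
    for s, e in segments:
        seg = x[s:e]
        peaks, _ = sps.find_peaks(seg, distance=dist)
        valleys, _ = sps.find_peaks(-seg, distance=dist)
        extrema = sorted(
            [(int(i), 1) for i in peaks] + [(int(i), -1) for i in valleys]
        )
        for (ia, ka), (ib, kb) in zip(extrema[:-1], extrema[1:]):
            if ka != kb:
                diffs.append(abs(seg[ia] - seg[ib]))
    return float(np.mean(diffs)) if diffs else float("nan")


def detrend_poly_tapered(
    values: np.ndarray, degree: int = 3, tapered: bool = True
) -> np.ndarray:
    """Remove a least-squares polynomial trend, optionally Hann-weighted.

    With ``tapered=True`` the squared residuals are weighted by a Hann
    taper over the segment, so the fit concentrates on the segment
    interior where the subsequent Hann-windowed periodogram draws its
    energy.  ``tapered=False`` is the plain unweighted detrend.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    deg = min(degree, n - 1)
    t = np.arange(n, dtype=float)
    if tapered:
        w = np.sqrt(sps.windows.hann(n, sym=True))  # polyfit squares the weights
        w = np.clip(w, 1e-6, None)
    else:
        w = None
    coeffs = np.polynomial.polynomial.polyfit(t, x, deg, w=w)
    return x - np.polynomial.polynomial.polyval(t, coeffs)


def psd_infraslow(
    values: np.ndarray,
    segments: list[tuple[int, int]],
    fs: float = 0.25,
    segment_length: float = 200.0,
    detrend_degree: int | None = None,
    tapered_detrend: bool = True,
    normalize: bool = True,
) -> PsdResult:
    """Infraslow PSD from equal-length consolidated NREMS bouts.

    Per bout the signal is centered and scaled to unit Euclidean norm,
    optionally detrended with a polynomial of degree <= ``detrend_degree``
    (Hann-taper-weighted by default; used for photometry, where residual
    bleaching survives the global correction), then a one-segment Welch
    periodogram with a Hann window is computed.  Bout periodograms are
    averaged and the result normalized to unit trapezoidal area.  With
    200-s bouts at 0.25 Hz the resolution is 0.005 Hz and Nyquist 0.125 Hz.
    """
    x = np.asarray(values, dtype=float)
    n_expected = int(round(segment_length * fs))
    if not segments:
        raise ValueError("no segments supplied")
    psds = []
    freqs = None
    for s, e in segments:
        if e - s != n_expected:
            raise ValueError(
                f"segment length {(e - s) / fs:.0f} s != required {segment_length:.0f} s"
            )
        seg = _unit_norm(x[s:e])
        if detrend_degree is not None:
            seg = detrend_poly_tapered(seg, detrend_degree, tapered=tapered_detrend)
        freqs, pxx = sps.welch(
            seg, fs=fs, window="hann", nperseg=seg.size, noverlap=0, detrend=False
        )
        psds.append(pxx)
    density = np.mean(psds, axis=0)
    if normalize:
        density = _normalize_unit_area(density, freqs)
    return PsdResult(freqs, density, segment_length, len(segments), normalized=normalize)


def _normalize_unit_area(density: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    area = np.trapezoid(np.clip(density, 0.0, None), freqs)
    if area <= 0:
        raise ValueError("PSD has non-positive area; cannot normalize")
    return density / area


def sigma_psd_baseline(
    psd: PsdResult, band: tuple[float, float] = (0.08, 0.12), normalize: bool = True
) -> PsdResult:
    """Zero the high-infraslow baseline of a sigma-band PSD.

    The mean density over ``band`` (default 0.08-0.12 Hz) is subtracted
    from every bin, bringing the ~0.02 Hz ISO peak to a baseline of 0,
    then the density is renormalized to unit area of its positive part
    (negative bins are retained in the output).
    """
    lo, hi = band
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    if not mask.any():
        raise ValueError(f"no frequency bins inside the baseline band [{lo}, {hi}] Hz")
    density = psd.density - psd.density[mask].mean()
    if normalize:
        density = _normalize_unit_area(density, psd.freqs)
    return PsdResult(
        psd.freqs,
        density,
        psd.segment_length,
        psd.n_segments,
        normalized=normalize,
        baseline_corrected=True,
    )
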