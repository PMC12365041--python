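"""Closed-loop NREMS-triggered stimulation: simulation and calibration.

The in-vivo protocol triggers a 50-s light train (10 Hz pulses) whenever
online EEG band powers indicate NREMS — slow (0.5-1 Hz) and sigma
(10-15 Hz) power both above per-animal thresholds — with a refractory
pause of at least 50 s after each train, so consecutive onsets are at
least 100 s apart.  Thresholds are tuned per animal so that triggers
land on average near sigma-ISO peaks.

The simulator replays that rule over an epoch-gridded recording.  It
sees only the band powers; the hypnogram and ground-truth ISO phase are
used exclusively to evaluate trigger specificity and phase preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .hypnogram import Hypnogram, detect_bouts
from .infraslow import lowpass_infraslow

__all__ = [
    "Thresholds",
    "StimulationLog",
    "simulate_stimulation",
    "calibrate_thresholds",
    "trigger_phase_stats",
]

LOGICS = ("and", "or")


@dataclass(frozen=True)
class Thresholds:
    """Detection thresholds on relative power (%) and their predicate."""

    sigma_threshold: float
    slow_threshold: float
    logic: str = "and"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma_threshold) and np.isfinite(self.slow_threshold)):
            raise ValueError("thresholds must be finite")
        if self.logic not in LOGICS:
            raise ValueError(f"logic must be one of {LOGICS}")

    def predicate(self, slow: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        hi_slow = np.asarray(slow) > self.slow_threshold
        hi_sigma = np.asarray(sigma) > self.sigma_threshold
        return hi_slow & hi_sigma if self.logic == "and" else hi_slow | hi_sigma


@dataclass(frozen=True)
class StimulationLog:
    """Closed-loop trigger onsets and train parameters.

    ``detection_epochs[i]`` is the epoch whose power readings caused
    onset ``i``; the onset itself starts ``latency_epochs`` later.
    Pulse-level structure (pulse rate / width) is metadata only: the
    simulation runs at epoch resolution.
    """

    onsets: np.ndarray  # seconds
    detection_epochs: np.ndarray
    train_duration: float = 50.0
    min_gap: float = 50.0
    pulse_rate: float = 10.0
    latency_epochs: int = 1

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        det = np.asarray(self.detection_epochs, dtype=int)
        if onsets.size and (np.diff(onsets) < self.train_duration + self.min_gap - 1e-9).any():
            raise ValueError("onsets closer than train_duration + min_gap")
        if onsets.size and (np.diff(onsets) <= 0).any():
            raise ValueError("onsets must be strictly increasing")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "detection_epochs", det)

    def __len__(self) -> int:
        return int(self.onsets.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.onsets, "duration_s": self.train_duration}
        )


def simulate_stimulation(
    powers: pd.DataFrame,
    thr: Thresholds,
    epoch_length: float = 4.0,
    start_time: float = 0.0,
    train_duration: float = 50.0,
    min_gap: float = 50.0,
    latency_epochs: int = 1,
    sustain_epochs: int = 1,
) -> StimulationLog:
    """Replay the closed-loop trigger rule over an epoch-power series.

    Epochs are scanned in time order; when the detection predicate has
    held for ``sustain_epochs`` consecutive epochs and at least
    ``train_duration + min_gap`` seconds have elapsed since the previous
    onset, a train is triggered with a processing latency of
    ``latency_epochs`` epochs after the detection epoch.  Only the power
    series is visible to the detector.
    """
    if thr is None:
        raise ValueError("thresholds must be set")
    for col in ("slow", "sigma"):
        if col not in powers.columns:
            raise ValueError(f"powers must contain a {col!r} column")
    hot = thr.predicate(powers["slow"].to_numpy(), powers["sigma"].to_numpy())
    refractory = train_duration + min_gap
    onsets: list[float] = []
    detections: list[int] = []
    last_onset = -np.inf
    run = 0
    for i, h in enumerate(hot):
        run = run + 1 if h else 0
        if run < sustain_epochs:
            continue
        onset = start_time + (i + latency_epochs) * epoch_length
        if onset - last_onset < refractory - 1e-9:
            continue
        onsets.append(onset)
        detections.append(i)
        last_onset = onset
        run = 0
    return StimulationLog(
        np.array(onsets),
        np.array(detections, dtype=int),
        train_duration=train_duration,
        min_gap=min_gap,
        latency_epochs=latency_epochs,
    )


def _estimate_iso_phase(rel_sigma: np.ndarray, fs: float = 0.25) -> np.ndarray:
    """Instantaneous sigma-ISO phase via the analytic signal.

    Convention: phase pi/2 at ISO peaks and -pi/2 at troughs (the
    generator's sine convention), obtained by rotating the analytic-signal
    angle of the lowpass-filtered, mean-subtracted sigma trace.
    """
    filt = lowpass_infraslow(rel_sigma, fs=fs)
    analytic = sps.hilbert(filt - filt.mean())
    return np.angle(analytic) + np.pi / 2


def calibrate_thresholds(
    powers: pd.DataFrame,
    hyp: Hypnogram,
    iso_phase: np.ndarray | None = None,
    peak_phase: float = np.pi / 2,
    slow_percentiles: np.ndarray | None = None,
    sigma_percentiles: np.ndarray | None = None,
    min_specificity: float = 0.95,
    min_triggers: int = 5,
    **sim_kwargs,
) -> tuple[Thresholds, dict]:
    """Grid-search thresholds that place triggers on sigma-ISO peaks.

    Candidate (slow, sigma) threshold pairs are taken from percentiles of
    the respective power distributions.  Each pair is simulated; pairs
    whose onsets fall in true-NREMS epochs less than ``min_specificity``
    of the time, or that yield fewer than ``min_triggers`` onsets, are
    discarded.  Among the rest the winner maximizes the mean circular
    alignment ``mean(cos(onset phase - peak_phase))`` of onset ISO
    phases.  ``iso_phase`` defaults to a Hilbert-transform estimate from
    the sigma trace itself.  Deterministic: no randomness involved.

    Returns the winning thresholds and a diagnostics dict
    (``specificity``, ``phase_score``, ``n_triggers``).
    """
    nrems_bouts = detect_bouts(hyp, state="N", merge_ma=True)
    if len(nrems_bouts) < 1 or not (hyp.scores == "N").any():
        raise ValueError("recording contains no NREMS; cannot calibrate")
    slow = powers["slow"].to_numpy()
    sigma = powers["sigma"].to_numpy()
    if iso_phase is None:
        iso_phase = _estimate_iso_phase(sigma)
        peak_phase = np.pi / 2
    if slow_percentiles is None:
        slow_percentiles = np.arange(20, 75, 10)
    if sigma_percentiles is None:
        sigma_percentiles = np.arange(50, 95, 5)
    is_nrems = hyp.scores == "N"
    n_epochs = len(hyp)
    best = None
    best_reject = (0.0, "no candidate produced enough triggers")
    for ps in slow_percentiles:
        thr_slow = float(np.percentile(slow, ps))
        for pg in sigma_percentiles:
            thr_sigma = float(np.percentile(sigma, pg))
            thr = Thresholds(sigma_threshold=thr_sigma, slow_threshold=thr_slow)
            log = simulate_stimulation(
                powers, thr, epoch_length=hyp.epoch_length,
                start_time=hyp.start_time, **sim_kwargs,
            )
            if len(log) < min_triggers:
                continue
            onset_epochs = np.minimum(
                log.detection_epochs + log.latency_epochs, n_epochs - 1
            )
            spec = float(is_nrems[onset_epochs].mean())
            if spec < min_specificity:
                if spec > best_reject[0]:
                    best_reject = (spec, f"best specificity {spec:.2f} at "
                                         f"slow p{ps}/sigma p{pg}")
                continue
            phases = iso_phase[onset_epochs[is_nrems[onset_epochs]]]
            score = float(np.cos(phases - peak_phase).mean()) if phases.size else -1.0
            if best is None or score > best[0]:
                best = (score, thr, spec, len(log))
    if best is None:
        raise ValueError(
            "no threshold pair met the NREMS-specificity constraint "
            f"({min_specificity:.0%}); {best_reject[1]}"
        )
    score, thr, spec, n = best
    return thr, {"phase_score": score, "specificity": spec, "n_triggers": n}


@dataclass(frozen=True)
class PhaseStats:
    """Circular statistics of trigger onsets on the sigma-ISO cycle."""

    circular_mean: float
    resultant_length: float
    fraction_rising: float
    n_onsets: int
    n_excluded: int = 0
    excluded_states: dict = field(default_factory=dict)


def trigger_phase_stats(
    log: StimulationLog,
    iso_phase: np.ndarray,
    hyp: Hypnogram,
    use_onset_epoch: bool = True,
) -> PhaseStats:
    """Circular summary of onset ISO phases.

    Onsets in non-NREMS epochs (where the ISO phase is undefined) are
    excluded from the circular statistics and tallied separately.  The
    rising fraction is the share of onsets on the rising half of the
    sine cycle, phase in (-pi/2, pi/2).
    """
    if len(log) == 0:
        return PhaseStats(float("nan"), float("nan"), float("nan"), 0)
    shift = log.latency_epochs if use_onset_epoch else 0
    epochs = np.minimum(log.detection_epochs + shift, len(hyp) - 1)
    in_nrems = hyp.scores[epochs] == "N"
    excluded = epochs[~in_nrems]
    states, counts = np.unique(hyp.scores[excluded], return_counts=True)
    phases = np.asarray(iso_phase)[epochs[in_nrems]]
    phases = phases[np.isfinite(phases)]
    if phases.size == 0:
        return PhaseStats(float("nan"), float("nan"), float("nan"), 0,
                          int((~in_nrems).sum()), dict(zip(states, counts.tolist())))
    vec = np.exp(1j * phases).mean()
    wrapped = np.angle(np.exp(1j * phases))
    rising = float(((wrapped > -np.pi / 2) & (wrapped < np.pi / 2)).mean())
    return PhaseStats(
        circular_mean=float(np.angle(vec)),
        resultant_length=float(np.abs(vec)),
        fraction_rising=rising,
        n_onsets=int(phases.size),
        n_excluded=int((~in_nrems).sum()),
        excluded_states=dict(zip(states, counts.tolist())),
    )
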