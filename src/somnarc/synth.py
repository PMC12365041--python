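"""Synthetic mouse NREMS recordings with known ground truth.

No public dataset backs this pipeline, so every downstream stage is
exercised against recordings generated here with fully known structure:

* a semi-Markov hypnogram over wake / NREMS / REMS with geometric
  (epoch-level) dwell times — REMS is entered only from NREMS;
* an infraslow oscillation (ISO) phase that advances only during NREMS
  (default period 50 s) and resets after long (> 60 s) wake;
* microarousals (MAs) inserted into NREMS as brief wake runs satisfying
  the MA rule exactly (<= 12 s, >= 16 s NREMS before, >= 4 s after), with
  per-epoch probability biased toward ISO troughs by a von Mises weight;
* per-epoch band powers: sigma modulated by the ISO and ramping into a
  surge before each REMS entry, delta elevated early in NREMS bouts,
  slow/delta declining just before REMS, and a wake/MA EMG-like
  full-band proxy;
* photometry: multiplicative polynomial bleaching, fluorescence drops in
  wake and REMS, and a NREMS CRH oscillation anti-phase (default) to the
  sigma ISO.  A ligand-insensitive "mut" variant keeps bleaching and
  artifacts but no CRH term.

Chain-generated wake runs directly after NREMS are drawn with a minimum
length of 4 epochs so that no accidental wake run can satisfy the MA
rule: the ground-truth MA list equals the MA detector's output exactly.

All randomness flows from ``SynthParams.seed``; identical parameters
give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bandpower import BANDS, EpochPowerSeries
from .hypnogram import Hypnogram
from .photometry import PhotometryTrace

__all__ = [
    "SynthParams",
    "GroundTruth",
    "generate_hypnogram",
    "generate_band_powers",
    "generate_photometry",
    "generate_recording",
]

#: MA rule constants in epochs (4-s grid): max run, NREMS before, NREMS after.
_MA_MAX_EP = 3
_MA_PRE_EP = 4
_MA_POST_EP = 1

#: ISO phase at troughs of sin(phase); MAs concentrate here.
TROUGH_PHASE = -np.pi / 2


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters; defaults emulate a light-phase mouse recording."""

    epoch_length: float = 4.0          # s
    recording_duration: float = 10800  # s (3 h)
    iso_period: float = 50.0           # s, ISO period T
    sigma_iso_amplitude: float = 0.4   # fraction of the NREMS sigma baseline
    crh_amplitude: float = 0.05        # dF/F units
    crh_phase_offset: float = np.pi    # rad vs the sigma ISO (pi = anti-phase)
    ma_rate_base: float = 12.0         # events per hour of NREMS
    ma_phase_concentration: float = 2.0  # von Mises kappa; 0 = phase-blind
    bleach_coeffs: tuple = (1.0, -2.5e-5, 8.0e-10)  # b0 + b1 t + b2 t^2
    state_artifact: dict = field(
        default_factory=lambda: {"W": -0.10, "R": -0.15, "M": -0.10}
    )
    surge_amplitude: float = 0.5       # fraction of the NREMS sigma baseline
    surge_duration: float = 32.0       # s
    dwell_mean: dict = field(
        default_factory=lambda: {"W": 60.0, "N": 160.0, "R": 60.0}
    )
    p_nrems_to_rems: float = 0.25
    noise_sd: dict = field(
        default_factory=lambda: {
            "slow": 0.05, "delta": 0.08, "sigma": 0.05, "full": 0.10,
            "photometry": 0.003,
        }
    )
    photometry_rate: float = 20.0      # Hz
    f0: float = 1.0                    # baseline fluorescence, a.u.
    long_wake_reset: float = 60.0      # s of wake after which the ISO phase resets
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.epoch_length > 0:
            raise ValueError("epoch_length must be positive")
        if not self.iso_period > 2 * self.epoch_length:
            raise ValueError("iso_period must exceed two epochs")
        if not 0 <= self.sigma_iso_amplitude < 1:
            raise ValueError("sigma_iso_amplitude must be in [0, 1)")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd values must be >= 0")
        if any(v < self.epoch_length for v in self.dwell_mean.values()):
            raise ValueError("dwell means must be at least one epoch")
        if self.ma_phase_concentration < 0:
            raise ValueError("ma_phase_concentration must be >= 0")

    @property
    def n_epochs(self) -> int:
        return int(self.recording_duration // self.epoch_length)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    scores: np.ndarray                 # pre-insertion truth with MA runs as 'W'
    iso_phase: np.ndarray              # rad at epoch start; NaN off-NREMS
    ma_onsets: list                    # (start epoch, length in epochs)
    bleach_coeffs: tuple
    sigma_noiseless: np.ndarray | None = None
    delta_noiseless: np.ndarray | None = None
    slow_noiseless: np.ndarray | None = None
    rems_entries: list = field(default_factory=list)  # first-REMS epoch indices
    surge_peaks: list = field(default_factory=list)   # (peak time s, amplitude)

    @property
    def ma_times(self) -> np.ndarray:
        """MA onset times in seconds (4-s grid)."""
        return np.array([s * 4.0 for s, _ in self.ma_onsets])


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _geometric_epochs(rng: np.random.Generator, mean_s: float, epoch_length: float,
                      minimum: int = 1) -> int:
    """Geometric dwell in epochs with the requested mean, floored at ``minimum``."""
    mean_ep = mean_s / epoch_length
    excess = mean_ep - minimum
    if excess <= 0:
        return minimum
    return minimum + rng.geometric(1.0 / (excess + 1.0)) - 1


def generate_hypnogram(params: SynthParams) -> tuple[Hypnogram, GroundTruth]:
    """Semi-Markov hypnogram with ISO phase and inserted microarousals.

    Returns the hypnogram (single W/N/R alphabet on disk: MA runs are
    written as wake) together with the ground truth (ISO phase per
    epoch, MA onsets, REMS entries).
    """
    n = params.n_epochs
    if n < 10:
        raise ValueError("recording_duration must cover at least 10 epochs")
    el = params.epoch_length
    rng_chain, rng_ma, _ = _rng_streams(params.seed, 3)

    # --- semi-Markov chain over W / N / R -------------------------------
    scores = np.empty(n, dtype="<U1")
    i, state = 0, "W"
    prev_sleep = None
    while i < n:
        if state == "W" and prev_sleep == "N":
            # post-NREMS wake must be >= 4 epochs, so it can never pass the MA rule
            dwell = _geometric_epochs(rng_chain, params.dwell_mean["W"], el,
                                      minimum=_MA_MAX_EP + 1)
        else:
            dwell = _geometric_epochs(rng_chain, params.dwell_mean[state], el)
        dwell = min(dwell, n - i)
        scores[i:i + dwell] = state
        i += dwell
        if state == "W":
            prev_sleep, state = "W", "N"
        elif state == "N":
            if rng_chain.random() < params.p_nrems_to_rems:
                prev_sleep, state = "N", "R"
            else:
                prev_sleep, state = "N", "W"
        else:  # REMS exits to wake
            prev_sleep, state = "R", "W"

    # --- ISO phase accumulator (advances only in NREMS) -----------------
    phase = np.full(n, np.nan)
    acc = 0.0
    dphi = 2 * np.pi * el / params.iso_period
    wake_run = 0
    for k in range(n):
        if scores[k] == "N":
            phase[k] = acc
            acc += dphi
            wake_run = 0
        else:
            if scores[k] == "W":
                wake_run += 1
                if wake_run * el > params.long_wake_reset:
                    acc = 0.0
            else:
                wake_run = 0

    # --- REMS entries (on the pre-MA truth) -----------------------------
    rems_entries = [
        k for k in range(1, n) if scores[k] == "R" and scores[k - 1] == "N"
    ]

    gt = GroundTruth(
        scores=scores.copy(),
        iso_phase=phase,
        ma_onsets=[],
        bleach_coeffs=params.bleach_coeffs,
        rems_entries=rems_entries,
    )

    # --- MA insertion ----------------------------------------------------
    out = scores.copy()
    if params.ma_rate_base > 0:
        _insert_mas(out, phase, params, rng_ma, gt)

    hyp = Hypnogram(out, epoch_length=el)
    return hyp, gt


def _insert_mas(scores: np.ndarray, phase: np.ndarray, params: SynthParams,
                rng: np.random.Generator, gt: GroundTruth) -> None:
    """Rewrite NREMS epochs to brief wake runs satisfying the MA rule.

    The event count is Poisson with mean ``ma_rate_base`` per hour of
    NREMS; onsets are drawn by von Mises-weighted sampling (concentrated
    at the ISO trough) over eligible epochs — those leaving >= 4 NREMS
    epochs before the run and >= 1 after — with candidates conflicting
    with an already-placed MA (less than 16 s of NREMS between events)
    rejected and redrawn, so the realized rate is unbiased.
    """
    el = params.epoch_length
    n = scores.size
    bouts = []
    k = 0
    while k < n:
        if scores[k] == "N":
            j = k
            while j < n and scores[j] == "N":
                j += 1
            bouts.append((k, j))
            k = j
        else:
            k += 1
    bout_end = {}
    eligible = []
    for s, e in bouts:
        # onset p allows an MA of at least 1 epoch: p-4 >= s and p+1 <= e-1
        for p in range(s + _MA_PRE_EP, e - 1):
            eligible.append(p)
            bout_end[p] = e
    total_nrems_s = sum((e - s) for s, e in bouts) * el
    if not eligible or total_nrems_s == 0:
        warnings.warn("no eligible NREMS epochs; MA insertion skipped")
        return
    expected = params.ma_rate_base * total_nrems_s / 3600.0
    n_target = int(rng.poisson(expected))
    if n_target == 0:
        return
    kappa = params.ma_phase_concentration
    w = np.ones(len(eligible))
    if kappa > 0:
        ph = phase[eligible]
        finite = np.isfinite(ph)
        w[finite] = np.exp(kappa * np.cos(ph[finite] - TROUGH_PHASE))
    order = rng.choice(len(eligible), size=len(eligible), replace=False, p=w / w.sum())
    placed: list[tuple[int, int]] = []  # (onset, length)
    for idx in order:
        if len(placed) >= n_target:
            break
        p = eligible[idx]
        e = bout_end[p]
        max_len = min(_MA_MAX_EP, e - 1 - p)
        length = int(rng.integers(1, max_len + 1))

        def conflicts(l: int) -> bool:
            for q, lq in placed:
                if q < p:
                    if p - (q + lq) < _MA_PRE_EP:  # < 16 s NREMS since last MA
                        return True
                elif q - (p + l) < _MA_PRE_EP:
                    return True
            return False

        if not conflicts(length):
            placed.append((p, length))
        elif length > 1 and not conflicts(1):
            placed.append((p, 1))  # a 1-epoch run still fits here
    for p, length in placed:
        scores[p:p + length] = "W"
    gt.ma_onsets = sorted(placed)


def generate_band_powers(
    hyp: Hypnogram, gt: GroundTruth, params: SynthParams
) -> EpochPowerSeries:
    """Per-epoch slow/delta/sigma/full band powers consistent with the truth.

    Sigma on NREMS epochs is ``baseline * (1 + A sin(ISO phase))`` plus a
    linear ramp reaching ``surge_amplitude * baseline`` at the last NREMS
    epoch before each REMS entry; delta decays from an elevated level
    early in NREMS bouts; slow and delta decline over the final 30 s
    before REMS entry; wake and MA epochs get an EMG-like high full-band
    floor with low sigma.  The full band is the sum of the named bands
    plus a non-negative broadband floor, so the energy bookkeeping
    ``mean(full) >= sum of band means`` holds by construction.
    """
    n = len(hyp)
    if gt.scores.size != n:
        raise ValueError("hypnogram and ground truth grids differ")
    el = hyp.epoch_length
    rng = _rng_streams(params.seed, 4)[2]
    truth = gt.scores  # pre-MA labels; MA epochs behave like wake below
    is_ma = (hyp.scores == "W") & (truth == "N")
    state = np.where(is_ma, "A", truth)  # A = microarousal

    base = {
        "sigma": {"W": 0.3, "N": 1.0, "R": 0.5, "A": 0.3},
        "delta": {"W": 0.5, "N": 2.0, "R": 0.4, "A": 0.6},
        "slow": {"W": 0.4, "N": 1.5, "R": 0.4, "A": 0.5},
    }
    emg_floor = {"W": 3.0, "N": 0.0, "R": 0.3, "A": 3.0}

    sigma = np.array([base["sigma"][s] for s in state])
    delta = np.array([base["delta"][s] for s in state])
    slow = np.array([base["slow"][s] for s in state])

    nrems = state == "N"
    phase = gt.iso_phase
    mod = np.where(nrems & np.isfinite(phase),
                   1.0 + params.sigma_iso_amplitude * np.sin(np.where(np.isfinite(phase), phase, 0.0)),
                   1.0)
    sigma = sigma * mod

    # delta elevated early in each NREMS bout (decays with 60-s constant)
    t_in_bout = np.full(n, np.nan)
    run = 0.0
    for k in range(n):
        if truth[k] == "N":
            t_in_bout[k] = run
            run += el
        else:
            run = 0.0
    delta = np.where(nrems, delta * (1.0 + 0.5 * np.exp(-np.nan_to_num(t_in_bout) / 60.0)), delta)

    # pre-REMS dynamics: sigma surge ramp, slow/delta decline
    gt.surge_peaks = []
    n_surge = int(round(params.surge_duration / el))
    for r in gt.rems_entries:
        lo = max(0, r - n_surge)
        for k in range(lo, r):
            if state[k] != "N":
                continue
            frac = 1.0 - (r - 1 - k) / max(1, n_surge - 1)
            sigma[k] += params.surge_amplitude * base["sigma"]["N"] * frac
            decline = 1.0 - 0.5 * frac
            slow[k] *= decline
            delta[k] *= decline
        if r > 0 and truth[r - 1] == "N":
            gt.surge_peaks.append(((r - 1) * el,
                                   params.surge_amplitude * base["sigma"]["N"]))

    gt.sigma_noiseless = sigma.copy()
    gt.delta_noiseless = delta.copy()
    gt.slow_noiseless = slow.copy()

    def noisy(x: np.ndarray, key: str) -> np.ndarray:
        sd = params.noise_sd.get(key, 0.0)
        if sd == 0:
            return x
        return np.clip(x + rng.normal(0.0, sd, x.size), 1e-6, None)

    sigma_n = noisy(sigma, "sigma")
    delta_n = noisy(delta, "delta")
    slow_n = noisy(slow, "slow")
    floor = 1.0 + np.array([emg_floor[s] for s in state])
    full = sigma_n + delta_n + slow_n + floor
    sd_full = params.noise_sd.get("full", 0.0)
    if sd_full:
        full = np.clip(full + rng.normal(0.0, sd_full, n), 1e-6, None)

    powers = pd.DataFrame(
        {"slow": slow_n, "delta": delta_n, "sigma": sigma_n, "full": full},
        columns=list(BANDS),
    )
    return EpochPowerSeries(hyp.times, powers)


def generate_photometry(
    hyp: Hypnogram, gt: GroundTruth, params: SynthParams, mut: bool = False
) -> PhotometryTrace:
    """Fluorescence trace with bleaching, state artifacts and CRH signal.

    ``F(t) = bleach(t) * F0 * (1 + artifact(state) + a_CRH sin(phase + phi)
    * 1[NREMS] + noise)``, where phase is the ISO phase interpolated to
    sample resolution.  ``mut=True`` zeroes the CRH amplitude while
    keeping bleaching, artifacts and the identical noise stream, which
    yields the ligand-insensitive control trace of the same recording.
    Non-positive samples are clipped to a small positive floor.
    """
    if params.photometry_rate < 1.0:
        raise ValueError("photometry sampling rate must be >= 1 Hz")
    rng = _rng_streams(params.seed, 4)[3]
    el = hyp.epoch_length
    dt = 1.0 / params.photometry_rate
    duration = len(hyp) * el
    t = np.arange(0.0, duration, dt)
    ep = np.minimum((t / el).astype(int), len(hyp) - 1)

    truth = gt.scores
    is_ma = (hyp.scores == "W") & (truth == "N")
    state = np.where(is_ma[ep], "M", truth[ep])

    artifact = np.zeros(t.size)
    for s, drop in params.state_artifact.items():
        artifact[state == s] = drop

    amp = 0.0 if mut else params.crh_amplitude
    signal = np.zeros(t.size)
    if amp != 0.0:
        nrems = state == "N"
        ph_epoch = gt.iso_phase[ep]
        within = t - ep * el
        ph = ph_epoch + 2 * np.pi * within / params.iso_period
        signal = np.where(nrems & np.isfinite(ph),
                          amp * np.sin(np.nan_to_num(ph) + params.crh_phase_offset),
                          0.0)

    b0, b1, b2 = params.bleach_coeffs
    bleach = b0 + b1 * t + b2 * t ** 2
    sd = params.noise_sd.get("photometry", 0.0)
    noise = rng.normal(0.0, sd, t.size) if sd > 0 else 0.0
    F = bleach * params.f0 * (1.0 + artifact + signal + noise)
    n_clip = int((F <= 0).sum())
    if n_clip:
        warnings.warn(f"{n_clip} non-positive fluorescence samples clipped")
        F = np.clip(F, 1e-9, None)
    return PhotometryTrace(t, F)


def generate_recording(params: SynthParams | None = None) -> dict:
    """One full synthetic recording: hypnogram, truth, powers, photometry.

    Returns a dict with keys ``hypnogram``, ``ground_truth``, ``powers``,
    ``photometry`` (CRH sensor) and ``photometry_mut`` (control sensor,
    same seed and artifacts, no CRH term).
    """
    if params is None:
        params = SynthParams()
    hyp, gt = generate_hypnogram(params)
    powers = generate_band_powers(hyp, gt, params)
    fp = generate_photometry(hyp, gt, params)
    fp_mut = generate_photometry(hyp, gt, params, mut=True)
    return {
        "params": params,
        "hypnogram": hyp,
        "ground_truth": gt,
        "powers": powers,
        "photometry": fp,
        "photometry_mut": fp_mut,
    }
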