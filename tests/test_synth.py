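"""Synthetic-recording generator: determinism, ground truth, structure."""

import warnings

import numpy as np
import pytest

import somnarc as sa
from somnarc.hypnogram import _runs
from oracles import ma_bruteforce


def _ma_runs(scores):
    return [(s, e - s) for lab, s, e in _runs(scores) if lab == "M"]


def test_identical_seed_gives_bit_identical_outputs():
    a = sa.generate_recording(sa.SynthParams(seed=42, recording_duration=3600))
    b = sa.generate_recording(sa.SynthParams(seed=42, recording_duration=3600))
    assert (a["hypnogram"].scores == b["hypnogram"].scores).all()
    assert a["powers"].powers.equals(b["powers"].powers)
    assert (a["photometry"].F == b["photometry"].F).all()
    c = sa.generate_recording(sa.SynthParams(seed=43, recording_duration=3600))
    assert not (a["hypnogram"].scores == c["hypnogram"].scores).all()


def test_zero_ma_rate_means_no_qualifying_wake_run():
    for seed in range(5):
        hyp, _ = sa.generate_hypnogram(sa.SynthParams(seed=seed, ma_rate_base=0.0))
        relabeled = ma_bruteforce(hyp.scores)
        assert not (relabeled == "M").any()


def test_ground_truth_mas_recovered_exactly():
    """Every inserted MA is found by the detector, and nothing else is."""
    for seed in range(5):
        hyp, gt = sa.generate_hypnogram(sa.SynthParams(seed=seed))
        scored = sa.reclassify_microarousals(hyp)
        assert _ma_runs(scored.scores) == sorted(gt.ma_onsets)
        assert len(gt.ma_onsets) > 0


def test_ma_rate_recovery():
    """Mean recovered MAs/h of NREMS within 2 SE of the nominal rate."""
    rates = []
    for seed in range(50):
        hyp, _ = sa.generate_hypnogram(sa.SynthParams(seed=seed))
        scored = sa.reclassify_microarousals(hyp)
        stats = sa.bout_statistics(scored, sa.detect_bouts(scored))
        rates.append(stats.mas_per_hour_nrems)
    rates = np.array(rates)
    se = rates.std(ddof=1) / np.sqrt(rates.size)
    assert abs(rates.mean() - 12.0) <= 2 * se


def test_ma_phase_preference_uniform_when_unbiased():
    """kappa=0: MA-onset ISO phases pass a Rayleigh uniformity test.

    The resultant length must stay below the 5% Rayleigh critical value
    (sqrt(-ln 0.05 / n)) in about 95% of replicates; the bound below is
    3 binomial SDs under that rate.
    """
    below = 0
    n_rep = 200
    for seed in range(n_rep):
        hyp, gt = sa.generate_hypnogram(
            sa.SynthParams(seed=seed, ma_phase_concentration=0.0)
        )
        scored = sa.reclassify_microarousals(hyp)
        onsets = [s for s, _ in gt.ma_onsets]
        phases = gt.iso_phase[onsets]  # truth phase is defined at MA onsets
        phases = phases[np.isfinite(phases)]
        if phases.size < 5:
            below += 1  # too few events to reject uniformity
            continue
        r = np.abs(np.exp(1j * phases).mean())
        below += r < np.sqrt(-np.log(0.05) / phases.size)
    assert below >= int(n_rep * (0.95 - 3 * np.sqrt(0.95 * 0.05 / n_rep)))


def test_ma_phase_preference_concentrates_at_trough():
    """Large kappa pulls MA onsets toward the ISO trough (phase -pi/2)."""
    all_phases = []
    for seed in range(20):
        hyp, gt = sa.generate_hypnogram(
            sa.SynthParams(seed=seed, ma_phase_concentration=8.0)
        )
        onsets = [s for s, _ in gt.ma_onsets]
        ph = gt.iso_phase[onsets]
        all_phases.extend(ph[np.isfinite(ph)])
    vec = np.exp(1j * np.array(all_phases)).mean()
    assert np.abs(vec) > 0.4
    assert abs(np.angle(vec * np.exp(1j * np.pi / 2))) < np.pi / 4


def test_rems_entered_only_from_nrems():
    for seed in range(10):
        hyp, _ = sa.generate_hypnogram(sa.SynthParams(seed=seed))
        s = hyp.scores
        prev = s[np.flatnonzero((s[1:] == "R") & (s[:-1] != "R"))]
        assert (prev == "N").all()


def test_short_recording_rejected():
    with pytest.raises(ValueError, match="10 epochs"):
        sa.generate_hypnogram(sa.SynthParams(recording_duration=30))


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        sa.SynthParams(iso_period=6.0)  # must exceed two epochs
    with pytest.raises(ValueError):
        sa.SynthParams(sigma_iso_amplitude=1.5)
    with pytest.raises(ValueError):
        sa.SynthParams(noise_sd={"sigma": -0.1})


# ---------------------------------------------------------------------------
# band powers


def _noiseless(seed=0, **kw):
    zero = {"slow": 0.0, "delta": 0.0, "sigma": 0.0, "full": 0.0, "photometry": 0.0}
    return sa.SynthParams(seed=seed, noise_sd=zero, **kw)


def test_sigma_constant_without_iso_modulation():
    p = _noiseless(sigma_iso_amplitude=0.0, surge_amplitude=0.0)
    hyp, gt = sa.generate_hypnogram(p)
    powers = sa.generate_band_powers(hyp, gt, p)
    sig = powers.powers["sigma"].to_numpy()
    nrems = (hyp.scores == "N") & (gt.scores == "N")
    assert np.ptp(sig[nrems]) < 1e-12


def test_iso_maxima_spacing_matches_period():
    p = _noiseless(surge_amplitude=0.0)
    hyp, gt = sa.generate_hypnogram(p)
    powers = sa.generate_band_powers(hyp, gt, p)
    sig = powers.powers["sigma"].to_numpy()
    bouts = sa.detect_bouts(hyp, state="N", merge_ma=False)
    long_bouts = bouts[bouts["duration_s"] > 150.0]
    assert len(long_bouts) > 0
    checked = 0
    for b in long_bouts.itertuples():
        seg = sig[b.start:b.end]
        peaks = np.flatnonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:])) + 1
        gaps = np.diff(peaks) * 4.0
        if gaps.size:
            assert (np.abs(gaps - 50.0) <= 4.0).all()
            checked += 1
    assert checked > 0


def test_energy_bookkeeping():
    for seed in range(5):
        p = sa.SynthParams(seed=seed)
        hyp, gt = sa.generate_hypnogram(p)
        powers = sa.generate_band_powers(hyp, gt, p).powers
        floor = powers["full"].mean() - (
            powers["slow"].mean() + powers["delta"].mean() + powers["sigma"].mean()
        )
        assert floor >= 0


def test_wake_epochs_have_high_full_low_sigma():
    p = sa.SynthParams(seed=1)
    hyp, gt = sa.generate_hypnogram(p)
    powers = sa.generate_band_powers(hyp, gt, p).powers
    wake = hyp.scores == "W"
    nrems = hyp.scores == "N"
    emg_proxy = powers["full"] - powers[["slow", "delta", "sigma"]].sum(axis=1)
    assert emg_proxy[wake].mean() > 2 * emg_proxy[nrems].mean()
    assert powers["sigma"][wake].mean() < powers["sigma"][nrems].mean()


# ---------------------------------------------------------------------------
# photometry


def test_mut_variant_identical_when_amplitude_zero():
    p = sa.SynthParams(seed=3, crh_amplitude=0.0)
    hyp, gt = sa.generate_hypnogram(p)
    a = sa.generate_photometry(hyp, gt, p)
    b = sa.generate_photometry(hyp, gt, p, mut=True)
    assert (a.F == b.F).all()


def test_pure_bleach_trace_flattens_to_zero_dff():
    """Degree-2 bleaching with no signal or noise: dF/F is identically 0."""
    p = _noiseless(crh_amplitude=0.0, state_artifact={"W": 0.0, "R": 0.0, "M": 0.0})
    hyp, gt = sa.generate_hypnogram(p)
    trace = sa.generate_photometry(hyp, gt, p)
    series = sa.downsample_to_epoch_rate(trace)
    n = min(series.values.size, len(hyp))
    series = sa.SampledSeries(series.time[:n], series.values[:n], series.rate)
    dff = sa.bleach_correct(series, hyp)
    assert np.abs(dff.dff).max() < 1e-9


def test_nonpositive_fluorescence_clipped_with_warning():
    p = sa.SynthParams(seed=0, bleach_coeffs=(1.0, -4e-4, 0.0))  # crosses zero at 2500 s
    hyp, gt = sa.generate_hypnogram(p)
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        trace = sa.generate_photometry(hyp, gt, p)
    assert (trace.F > 0).all()
    assert any("clipped" in str(w.message) for w in rec)
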