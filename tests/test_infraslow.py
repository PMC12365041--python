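"""Infraslow filtering, cross-correlation, peak-to-peak and PSD."""

import numpy as np
import pytest
from scipy import signal as sps

import somnarc as sa
from somnarc.infraslow import design_lowpass
from oracles import crosscorr_lag_scan

FS = 0.25


def _sine(freq, n=2000, fs=FS, phase=0.0):
    t = np.arange(n) / fs
    return np.sin(2 * np.pi * freq * t + phase)


# ---------------------------------------------------------------------------
# zero-phase FIR lowpass


def test_unity_dc_gain():
    x = np.full(1000, 3.7)
    assert np.abs(sa.lowpass_infraslow(x) - 3.7).max() < 1e-9


def test_stopband_attenuation():
    x = _sine(0.1)
    y = sa.lowpass_infraslow(x)
    core = slice(400, -400)  # ignore edges
    assert np.sqrt(np.mean(y[core] ** 2)) < 0.05 * np.sqrt(np.mean(x[core] ** 2))


def test_passband_amplitude_and_zero_phase():
    x = _sine(0.01, n=4000)
    y = sa.lowpass_infraslow(x)
    core = slice(500, -500)
    rms_ratio = np.sqrt(np.mean(y[core] ** 2)) / np.sqrt(np.mean(x[core] ** 2))
    assert abs(rms_ratio - 1.0) < 0.05
    px, _ = sps.find_peaks(x[core])
    py, _ = sps.find_peaks(y[core])
    assert len(px) == len(py)
    assert np.abs(px - py).max() <= 1  # zero phase shift at the peaks


def test_short_series_rejected_with_minimum():
    with pytest.raises(ValueError, match="> 300 samples"):
        sa.lowpass_infraslow(np.zeros(200))


def test_filter_design_matches_windowed_sinc():
    b = design_lowpass()
    w, h = sps.freqz(b, worN=2048, fs=FS)
    assert abs(np.abs(h[0]) - 1.0) < 1e-9
    assert np.abs(h[w > 0.06]).max() < 0.01


# ---------------------------------------------------------------------------
# cross-correlation


def test_anti_identical_signals_give_minus_one():
    x = _sine(0.02, n=400)
    res = sa.crosscorrelate_segments(x, -x, [(50, 150), (200, 300)])
    assert res.r_lag0 == pytest.approx(-1.0, abs=1e-9)
    assert res.lag_at_max == 0.0


def test_self_correlation_is_one_at_zero_lag():
    rng = np.random.default_rng(0)
    x = rng.normal(size=500)
    res = sa.crosscorrelate_segments(x, x, [(0, 500)])
    assert res.r_lag0 == pytest.approx(1.0, abs=1e-9)
    assert res.lag_at_max == 0.0


def test_imposed_shift_recovered_with_sign_convention():
    """y = x shifted by +3 samples means x precedes y: lag_at_max = -12 s."""
    rng = np.random.default_rng(1)
    base = sa.lowpass_infraslow(rng.normal(size=1200))
    x = base[3:1003]
    y = base[0:1000]  # y[n] = x[n-3]
    res = sa.crosscorrelate_segments(x, y, [(0, 1000)])
    assert res.lag_at_max == pytest.approx(-12.0)
    shift, r = crosscorr_lag_scan(x, y, max_shift=25)
    assert shift * 4.0 == pytest.approx(res.lag_at_max)
    assert res.r_max == pytest.approx(r, abs=0.05)


def test_white_noise_null_level():
    """Independent channels: |r_lag0| below 3/sqrt(L) in >=95% of replicates."""
    L, ok = 50, 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=L * 50)
        y = rng.normal(size=L * 50)
        segs = [(i * L, (i + 1) * L) for i in range(50)]
        res = sa.crosscorrelate_segments(x, y, segs)
        ok += abs(res.r_lag0) < 3 / np.sqrt(L)
    assert ok >= 95


def test_unequal_segments_rejected():
    x = np.zeros(100)
    with pytest.raises(ValueError, match="unequal"):
        sa.crosscorrelate_segments(x, x, [(0, 10), (20, 35)])


def test_empty_segment_list_flagged():
    with pytest.warns(UserWarning, match="no segments"):
        res = sa.crosscorrelate_segments(np.zeros(10), np.zeros(10), [])
    assert res.n_segments == 0 and np.isnan(res.r_lag0)


# ---------------------------------------------------------------------------
# peak-to-peak


def test_sinusoid_peak_to_peak():
    """50-s period, amplitude 1: mean adjacent peak-valley difference ~ 2."""
    x = _sine(1 / 50.0, n=3000)
    segs = [(i * 35 + 100, (i + 1) * 35 + 100) for i in range(20)]  # 140-s segments
    p2p = sa.peak_to_peak(x, segs)
    assert p2p == pytest.approx(2.0, abs=0.05)


def test_constant_series_gives_missing():
    assert np.isnan(sa.peak_to_peak(np.ones(500), [(0, 100)]))


def test_min_separation_enforced():
    # 10-s period oscillation: extrema closer than 40 s are not all kept
    x = _sine(0.1, n=500)
    segs = [(0, 200)]
    dist = int(40.0 * FS)
    peaks, _ = sps.find_peaks(x[0:200], distance=dist)
    assert (np.diff(peaks) >= dist).all()


# ---------------------------------------------------------------------------
# infraslow PSD


def _segments(n_seg, L=50, gap=10):
    return [(i * (L + gap), i * (L + gap) + L) for i in range(n_seg)]


def test_sinusoid_psd_peak_in_exact_bin():
    segs = _segments(10)
    n = segs[-1][1]
    x = _sine(0.02, n=n)
    res = sa.psd_infraslow(x, segs)
    assert res.freqs[np.argmax(res.density)] == pytest.approx(0.020)
    assert res.freqs[1] - res.freqs[0] == pytest.approx(0.005)
    assert res.freqs[-1] == pytest.approx(0.125)


def test_unit_area_normalization():
    rng = np.random.default_rng(5)
    x = rng.normal(size=1000)
    res = sa.psd_infraslow(x, _segments(10))
    assert np.trapezoid(res.density, res.freqs) == pytest.approx(1.0, abs=1e-9)


def test_white_noise_psd_flat():
    """200 white-noise bouts: interior bins flat within 3 SE of the mean."""
    rng = np.random.default_rng(11)
    segs = _segments(200, gap=0)
    x = rng.normal(size=segs[-1][1])
    per_seg = np.stack(
        [sa.psd_infraslow(x, [s], normalize=False).density for s in segs]
    )
    res = sa.psd_infraslow(x, segs, normalize=False)
    assert np.allclose(res.density, per_seg.mean(axis=0))
    interior = (res.freqs > 0.01) & (res.freqs < 0.125)
    d = res.density[interior]
    se = per_seg.std(axis=0, ddof=1)[interior] / np.sqrt(len(segs))
    assert (np.abs(d - d.mean()) < 3 * se).all()


def test_wrong_segment_length_rejected():
    with pytest.raises(ValueError, match="segment length"):
        sa.psd_infraslow(np.zeros(100), [(0, 40)])


def test_detrend_removes_cubic_trend():
    t = np.linspace(-1, 1, 50)
    trend = 0.5 + 0.3 * t - 0.2 * t**2 + 0.4 * t**3
    x = np.tile(trend, 4)
    res_raw = sa.psd_infraslow(x, _segments(4, gap=0), normalize=False)
    res_det = sa.psd_infraslow(
        x, _segments(4, gap=0), detrend_degree=3, normalize=False
    )
    assert res_det.density.sum() < 1e-3 * res_raw.density.sum()


# ---------------------------------------------------------------------------
# sigma-PSD baseline correction


def test_baseline_subtraction_identity_when_already_zero():
    freqs = np.arange(0, 0.13, 0.005)
    density = np.zeros_like(freqs)
    density[4] = 1.0  # 0.02 Hz peak, zero elsewhere incl. 0.08-0.12
    psd = sa.PsdResult(freqs, density, 200.0, 1, normalized=False)
    out = sa.sigma_psd_baseline(psd, normalize=False)
    assert np.allclose(out.density, density)


def test_constant_density_degenerates_informatively():
    freqs = np.arange(0, 0.13, 0.005)
    psd = sa.PsdResult(freqs, np.ones_like(freqs), 200.0, 1, normalized=False)
    with pytest.raises(ValueError, match="non-positive area"):
        sa.sigma_psd_baseline(psd)


def test_end_to_end_sigma_baseline():
    segs = _segments(10)
    x = _sine(0.02, n=segs[-1][1]) + 0.3
    raw = sa.psd_infraslow(x, segs, normalize=False)
    out = sa.sigma_psd_baseline(raw)
    band = (out.freqs >= 0.08) & (out.freqs <= 0.12)
    area = np.trapezoid(np.clip(out.density, 0, None), out.freqs)
    assert area == pytest.approx(1.0, abs=1e-9)
    assert out.freqs[np.argmax(out.density)] == pytest.approx(0.020)
    # the subtracted band averages to zero on the pre-normalization scale
    pre = raw.density - raw.density[band].mean()
    assert abs(pre[band].mean()) < 1e-9
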