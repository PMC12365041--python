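"""End-to-end pipeline: scoring -> architecture -> dF/F -> infraslow ->
surge -> closed loop.

:func:`run_pipeline` chains the stages over loaded inputs or a synthetic
recording, writes JSON/TSV/CSV results to the configured output
directory and returns the result bundle in memory.  Every output file
carries the config hash and seed, and a run log records per-stage counts
(epochs read, bouts found, segments used, triggers issued), so a run can
be reproduced exactly from its artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import bandpower as bp
from . import closed_loop as cl
from . import hypnogram as hg
from . import infraslow as isl
from . import io as sio
from . import photometry as ph
from . import synth
from .config import PipelineConfig

logger = logging.getLogger("somnarc")

__all__ = ["run_pipeline", "preprocess_photometry"]


def preprocess_photometry(
    trace: ph.PhotometryTrace, hyp: hg.Hypnogram, scope: str = "all_nrem"
) -> ph.DffSeries:
    """Raw trace -> epoch-rate dF/F with z-score (the full FP recipe)."""
    series = ph.downsample_to_epoch_rate(trace, start_time=hyp.start_time)
    n = min(series.values.size, len(hyp))
    series = ph.SampledSeries(series.time[:n], series.values[:n], series.rate)
    dff = ph.bleach_correct(series, hyp)
    return ph.zscore_nrem(dff, hyp, scope=scope)


def run_pipeline(
    config: PipelineConfig | None = None,
    hypnogram: hg.Hypnogram | None = None,
    powers: bp.EpochPowerSeries | None = None,
    photometry: ph.PhotometryTrace | None = None,
    photometry_mut: ph.PhotometryTrace | None = None,
    simulate: bool = False,
    synth_params: "synth.SynthParams | None" = None,
    output_dir: str | Path | None = None,
    write_outputs: bool = True,
    required_stages: tuple = (),
) -> dict:
    """Run every configured stage and collect the result bundle.

    With ``simulate=True`` the inputs are generated by the synthetic
    module (seeded from the config); otherwise a hypnogram is required,
    band powers enable the spectral/surge/closed-loop stages and
    photometry enables the dF/F and cross-correlation stages.  Raises
    before execution when a requested stage is missing its input.
    """
    cfg = config or PipelineConfig()
    results: dict = {"config_hash": cfg.config_hash, "seed": cfg.seed}
    gt = None
    if simulate:
        params = synth_params or synth.SynthParams(seed=cfg.seed)
        bundle = synth.generate_recording(params)
        hypnogram = bundle["hypnogram"]
        gt = bundle["ground_truth"]
        powers = bundle["powers"]
        photometry = bundle["photometry"]
        photometry_mut = bundle["photometry_mut"]
    if hypnogram is None:
        raise ValueError("a hypnogram is required (or pass simulate=True)")
    _needs = {
        "isocorr": (photometry, "photometry"), "p2p": (photometry, "photometry"),
        "psd": (photometry, "photometry"), "dff": (photometry, "photometry"),
        "relpower": (powers, "band powers"), "surge": (powers, "band powers"),
        "stim-sim": (powers, "band powers"),
    }
    for stage in required_stages:
        if stage not in _needs:
            raise ValueError(f"unknown stage {stage!r}")
        inp, name = _needs[stage]
        if inp is None:
            raise ValueError(f"stage {stage!r} requested but no {name} supplied")

    meta = {"config_hash": cfg.config_hash, "seed": cfg.seed}
    outdir = Path(output_dir or cfg.output_dir)

    # --- MA scoring and sleep architecture ------------------------------
    hyp = hg.reclassify_microarousals(hypnogram)
    bouts = hg.detect_bouts(hyp, min_duration=cfg.min_bout_s, merge_ma=True)
    stats = hg.bout_statistics(hyp, bouts)
    results["hypnogram"] = hyp
    results["bouts"] = bouts
    results["bout_stats"] = stats
    logger.info("ma-score: %d epochs, %d MA events, %d bouts",
                len(hyp), hg.count_ma_events(hyp), len(bouts))

    # --- photometry preprocessing ---------------------------------------
    dff = dff_mut = None
    if photometry is not None:
        dff = preprocess_photometry(photometry, hyp, scope=cfg.zscore_scope)
        results["dff"] = dff
    if photometry_mut is not None:
        dff_mut = preprocess_photometry(photometry_mut, hyp, scope=cfg.zscore_scope)
        results["dff_mut"] = dff_mut

    # --- relative powers, state means, surge ----------------------------
    rel = None
    if powers is not None:
        if len(powers) != len(hyp):
            raise ValueError("band powers and hypnogram are not aligned")
        rel = bp.relative_band_power(powers)
        results["relative_powers"] = rel
        results["state_means"] = bp.state_mean_power(
            rel, hyp, min_bout=cfg.state_mean_min_bout_s
        )
        transitions = hg.detect_transitions(hyp, min_epochs=cfg.transition_min_epochs)
        results["transitions"] = transitions
        if transitions:
            results["surge"] = bp.sigma_surge(
                rel["sigma"].to_numpy(), hyp, transitions
            )
        logger.info("relpower/surge: %d transitions", len(transitions))

    # --- infraslow cross-correlation / p2p / PSD ------------------------
    fs = 1.0 / cfg.epoch_length
    if rel is not None and dff is not None:
        sig_f = isl.lowpass_infraslow(
            rel["sigma"].to_numpy(), fs=fs, cutoff=cfg.filter_cutoff, taps=cfg.filter_taps
        )
        crh_f = isl.lowpass_infraslow(
            dff.z if dff.z is not None else dff.dff,
            fs=fs, cutoff=cfg.filter_cutoff, taps=cfg.filter_taps,
        )
        xseg = hg.extract_segments(hyp, **cfg.xcorr_segments.kwargs())
        if xseg:
            results["crosscorr"] = isl.crosscorrelate_segments(crh_f, sig_f, xseg, fs=fs)
        # sensor amplitude comparison runs on dF/F, not z: standardizing each
        # sensor to unit NREMS SD would erase the very contrast being measured
        pseg = hg.extract_segments(hyp, **cfg.p2p_segments.kwargs())
        dff_f = isl.lowpass_infraslow(
            dff.dff, fs=fs, cutoff=cfg.filter_cutoff, taps=cfg.filter_taps
        )
        results["p2p_crh"] = isl.peak_to_peak(
            dff_f, pseg, fs=fs, min_separation=cfg.p2p_min_separation
        )
        if dff_mut is not None:
            mut_f = isl.lowpass_infraslow(
                dff_mut.dff, fs=fs, cutoff=cfg.filter_cutoff, taps=cfg.filter_taps
            )
            results["p2p_mut"] = isl.peak_to_peak(
                mut_f, pseg, fs=fs, min_separation=cfg.p2p_min_separation
            )
        # PSDs run on the unfiltered series (per-segment detrend handles trends);
        # the 0.025-Hz lowpass would suppress ISO periods shorter than 40 s
        sseg = hg.extract_segments(hyp, **cfg.psd_segments.kwargs())
        if sseg:
            results["psd_crh"] = isl.psd_infraslow(
                dff.z if dff.z is not None else dff.dff,
                sseg, fs=fs, detrend_degree=3,
            )
            sigma_psd = isl.psd_infraslow(
                rel["sigma"].to_numpy(), sseg, fs=fs, normalize=False
            )
            results["psd_sigma"] = isl.sigma_psd_baseline(sigma_psd)
        logger.info("infraslow: %d xcorr segs, %d p2p segs, %d psd segs",
                    len(xseg), len(pseg), len(sseg) if sseg else 0)

    # --- closed-loop simulation -----------------------------------------
    if rel is not None:
        iso_phase = gt.iso_phase if gt is not None else None
        try:
            thr, diag = cl.calibrate_thresholds(rel, hyp, iso_phase=iso_phase)
        except ValueError as exc:
            logger.warning("stim-sim: calibration failed (%s)", exc)
        else:
            log = cl.simulate_stimulation(
                rel, thr, epoch_length=cfg.epoch_length,
                start_time=hyp.start_time,
                train_duration=cfg.train_duration, min_gap=cfg.min_gap,
            )
            results["thresholds"] = thr
            results["stim_log"] = log
            results["stim_diag"] = diag
            if iso_phase is not None:
                results["stim_phase_stats"] = cl.trigger_phase_stats(log, iso_phase, hyp)
            logger.info("stim-sim: %d triggers, specificity %.2f",
                        len(log), diag["specificity"])

    if write_outputs:
        _write_bundle(results, outdir, meta, cfg)
    return results


def _write_bundle(results: dict, outdir: Path, meta: dict, cfg: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    sio.write_hypnogram(results["hypnogram"], outdir / "hypnogram_ma.csv", meta)
    results["bouts"].to_csv(outdir / "bouts.tsv", sep="\t", index=False)
    summary: dict = {
        "config_hash": meta["config_hash"],
        "seed": meta["seed"],
        "config": cfg.to_dict(),
        "bout_stats": results["bout_stats"].to_dict(),
    }
    if "dff" in results:
        sio.write_dff(results["dff"], outdir / "dff.csv", meta)
        summary["bleach_fit_coeffs"] = results["dff"].fit_coeffs.tolist()
    if "crosscorr" in results:
        xc = results["crosscorr"]
        summary["crosscorr"] = {
            "r_lag0": xc.r_lag0, "r_max": xc.r_max,
            "lag_at_max_s": xc.lag_at_max, "n_segments": xc.n_segments,
            "lags_s": xc.lags, "mean_corr": xc.mean_corr,
        }
    for key in ("p2p_crh", "p2p_mut"):
        if key in results:
            summary[key] = results[key]
    for key in ("psd_crh", "psd_sigma"):
        if key in results:
            p = results[key]
            summary[key] = {"freqs_hz": p.freqs, "density": p.density,
                            "n_segments": p.n_segments,
                            "baseline_corrected": p.baseline_corrected}
    if "surge" in results:
        s = results["surge"]
        summary["surge"] = {
            "peak_amplitude_pct": s.peak_amplitude,
            "latency_to_rems_s": s.latency_to_rems,
            "n_transitions": s.n_transitions,
        }
    if "state_means" in results:
        summary["state_mean_relative_power_pct"] = {
            state: dict(zip(results["state_means"].columns, row))
            for state, row in results["state_means"].iterrows()
        }
    if "stim_log" in results:
        sio.write_stim_log(results["stim_log"], outdir / "stimulation_log.csv", meta)
        summary["stimulation"] = {
            "thresholds": asdict(results["thresholds"]),
            "n_triggers": len(results["stim_log"]),
            **results["stim_diag"],
        }
        if "stim_phase_stats" in results:
            ps = results["stim_phase_stats"]
            summary["stimulation"]["phase_stats"] = asdict(ps)
    sio.write_json(_sanitize(summary), outdir / "results.json")


def _sanitize(obj):
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return _sanitize(obj.item())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
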