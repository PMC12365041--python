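# somnarc

Analysis of mouse NREM-sleep microarchitecture from polysomnography
(EEG/EMG hypnograms + band powers) combined with fiber photometry of
neuromodulator release — built around the infraslow oscillation (ISO) of
sleep-spindle activity and its relationship to CRH release in the
thalamic reticular nucleus.

## What it computes

During consolidated NREM sleep (NREMS), EEG sigma power (10–15 Hz, a
proxy for spindle density) waxes and wanes with a ~50-s period
(~0.02 Hz).  CRH release, reported by a GRAB fluorescence sensor,
oscillates on the same timescale in anti-phase: CRH peaks coincide with
the fragility phase of the ISO, where microarousals (MAs) preferentially
occur.  The package implements the full analysis chain:

* **Microarousal scoring** — wake runs of ≤ 12 s preceded by ≥ 16 s and
  followed by ≥ 4 s of NREMS are relabeled `M`; bout detection merges
  them back into their NREMS bout ("regardless of MAs").
* **Sleep architecture** — per-state bout lengths, % of recording, bout
  counts/h and MAs per hour of NREMS.
* **Photometry ΔF/F** — raw fluorescence is resampled to the 0.25-Hz
  epoch grid, a degree-2 bleaching polynomial is least-squares fitted on
  NREMS samples only, and ΔF/F = (F − fit)/fit is z-scored against the
  NREMS mean/SD:  z = (x − μ_NREMS)/σ_NREMS.
* **Infraslow analysis** — zero-phase FIR lowpass (0.025 Hz, 100 taps);
  segment-wise cross-correlation of CRH vs sigma over consolidated NREMS
  bouts (> 300 s, first 100 s discarded, cut to 200 s), reporting r at
  lag 0, the signed maximum |r| near zero lag, and its lag; peak-to-peak
  amplitudes (extrema ≥ 40 s apart) over trimmed ≥ 150-s bouts; and
  one-segment Welch PSDs (Hann window, 200-s bouts, 0.005-Hz
  resolution) normalized to unit area, with the sigma-band PSD baselined
  on its 0.08–0.12 Hz mean.
* **Sigma surge** — at NREMS→REMS transitions (≥ 5 epochs each side),
  the averaged, 10-Hz-upsampled relative sigma trace is searched for its
  highest peak in the last 50 s of NREMS; amplitude and latency to REMS
  entry are reported.
* **Closed-loop stimulation** — simulation of NREMS-triggered 50-s light
  trains gated by slow- and sigma-power thresholds with a 50-s
  refractory gap, plus per-recording threshold calibration that places
  triggers on sigma-ISO peaks.
* **Synthetic recordings** — a seeded generator (semi-Markov vigilance
  states, NREMS-gated ISO phase, trough-biased MA insertion, bleaching +
  artifacts + anti-phase CRH photometry) provides ground truth for every
  stage; no external data are needed.

## Worked example

```python
import somnarc as sa

res = sa.run_pipeline(simulate=True, write_outputs=False)
xc = res["crosscorr"]
print(f"r(0) = {xc.r_lag0:.2f} over {xc.n_segments} NREMS segments")
print(f"p2p dF/F: CRH {res['p2p_crh']:.3f} vs mut {res['p2p_mut']:.3f}")
print(f"MAs/h NREMS: {res['bout_stats'].mas_per_hour_nrems:.1f}")
```

prints (default 3-h recording, seed 0):

```
r(0) = -0.87 over 8 NREMS segments
p2p dF/F: CRH 0.084 vs mut 0.018
MAs/h NREMS: 13.2
```

The negative zero-lag correlation is the anti-phase relationship between
CRH release and sigma power; the CRH sensor's infraslow peak-to-peak
amplitude is several-fold that of the ligand-insensitive control
(`mut`), which retains only bleaching, artifacts and noise; the MA rate
is the generator's nominal 12/h plus sampling noise.

The same stages are available from a shell:

```bash
somnarc simulate --seed 1 --out syn
somnarc ma-score syn/hypnogram.csv
somnarc isocorr syn/photometry.csv syn/band_powers.csv syn/hypnogram_ma.csv
somnarc run --simulate --out results/
```

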