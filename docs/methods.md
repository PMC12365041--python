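# Methods

This note documents the models and procedures implemented in `somnarc`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show
about real recordings.

## Epoch grid and vigilance states

All analyses run on a fixed 4-s epoch grid (0.25 Hz); epoch *i* spans
the half-open interval [4*i*, 4(*i*+1)) s.  Scores come from the
four-letter alphabet W (wake), N (NREMS), R (REMS), M (microarousal).
On disk raw hypnograms use only W/N/R; M is assigned by the scoring
step.

**Microarousal rule.**  A maximal wake run is relabeled M when all
three conditions hold literally: run duration ≤ 12 s (≤ 3 epochs);
the 16 s immediately before are all N; the 4 s immediately after are N.
Runs touching either recording edge are never relabeled — their flanking
conditions are unverifiable, and the conservative reading keeps the
scorer deterministic.  The operation is idempotent and never touches
N or R epochs.  The epoch after an MA must be exactly N (not merely
non-wake); that is the strict reading of the rule and the one the
brute-force oracle in the test suite enumerates.

**Bouts and statistics.**  Bouts are maximal runs of one state; with
MA-merging, M epochs do not break an N run and are tallied per bout.
Thresholds follow the wording they come from: "longer than 300 s" is
strict, "at least 150 s" and "at least 4 s" are inclusive.  The MA rate
denominator ("per hour of NREMS") includes MA epochs merged into NREMS
bouts, since they occur inside NREMS; a flag excludes them.  Percentages
per state are computed from the supplied bout table, so with the default
recipe (MA-merged, 4-s minimum) the three macro-states partition the
recording and sum to exactly 100%.  Distinct MA events separated by a
single NREMS stretch count separately (events are maximal M runs).

## Photometry preprocessing

The raw fluorescence trace is brought to the epoch grid by plain linear
interpolation at the grid timestamps (no anti-alias filter; a
one-step moving-average pre-filter is available behind a flag).  A 1-s
"envelope" via monotone piecewise-cubic (PCHIP) interpolation is
provided for display and peak alignment only — every analysis operates
on the 0.25-Hz series.

Bleaching is removed multiplicatively: a degree-2 polynomial is fitted
by ordinary least squares to (t, F) pairs restricted to strict-N epochs
(M excluded), evaluated over the whole recording, and
ΔF/F = (F − fit)/fit.  Fitting on NREMS only keeps the wake/REMS
fluorescence drops (pH/hemodynamic artifacts common to GRAB sensors and
their ligand-insensitive mutants) out of the baseline.  The procedure is
exactly scale-invariant (F → cF leaves ΔF/F unchanged) and reproduces a
pure degree-2 decay to machine precision.  A fitted baseline that
touches zero anywhere raises an error naming the first offending time.

z-scoring standardizes against the NREMS mean and population SD
(ddof = 0; the distinction from the sample SD is negligible at these
sample sizes) and is applied to all samples in scope.  The default scope
is the whole recording ("all_nrem"); "per_section" splits at wake runs
longer than 60 s and standardizes each section independently — useful
when sensor sensitivity drifts across long recordings.

**Where z is and is not used.**  Cross-correlation and PSD shapes are
scale-free, so they run on z.  The CRH-vs-control peak-to-peak
comparison runs on ΔF/F: standardizing each sensor to unit NREMS SD
would erase the amplitude contrast being measured and, worse, amplify
the control sensor's noise floor by 1/σ, inverting the expected
direction.  This is the package's reading of "z-scoring … depending on
the situation".

## Infraslow analysis

**Filter.**  Hamming-windowed-sinc FIR, 100 taps, 0.025-Hz cutoff at
fs = 0.25 Hz, applied forward–backward (zero phase, odd-reflection
padding of 3 × taps = 300 samples).  Filtering is applied to the full
recording *before* segment extraction; per-bout filtering is impossible
at 50–75 samples against a 300-sample padding requirement, and a
regression test pins this order.

**Segments.**  Cross-correlation and PSD use MA-merged NREMS runs
> 300 s with the first 100 s removed (wake→NREMS transition) and cut to
200 s; peak-to-peak uses runs ≥ 150 s trimmed by 16 s/4 s.  Segments
whose trimmed length falls short of the cut are dropped, never padded.

**Cross-correlation.**  Per segment both channels are centered and
scaled to unit Euclidean norm, so the zero-lag value is the Pearson r;
full cross-correlations are aligned at lag 0 and averaged.  Sign
convention: positive lag means CRH follows sigma.  The summary "max
corr" is the signed value of largest magnitude within ±100 s of zero lag
(the window is a package choice; the anti-phase extremum sits at lag 0,
and ±2 ISO periods bound any physiologically meaningful shift).  No
per-lag overlap correction is applied, so the curve is biased toward
zero at large |lag|; all summary statistics live near lag 0 where the
bias is negligible.

**Peak-to-peak.**  Peaks and valleys are detected independently with a
40-s minimum distance, interleaved by time; every adjacent
opposite-kind pair contributes |peak − valley|, and the recording value
is the mean over pairs.  No extrema → missing, not zero.

**PSD.**  Per 200-s segment (50 samples): center and unit-norm scale,
optional polynomial detrend of degree ≤ 3 (photometry only — residual
bleaching curvature survives the global fit), Hann window, one-segment
Welch periodogram; average across segments; normalize to unit
trapezoidal area.  Resolution 0.005 Hz, Nyquist 0.125 Hz; a 50-s ISO
lands exactly in the 0.020-Hz bin.  The "Hann-applied" detrend is
implemented as Hann-taper-weighted least squares (weights concentrate
the fit where the subsequent taper draws its energy); a plain unweighted
detrend is available behind a flag.  The PSD path does **not** apply the
0.025-Hz lowpass — it would suppress ISO periods shorter than 40 s that
the PSD is supposed to resolve.  The sigma-band PSD is baselined by
subtracting its 0.08–0.12-Hz mean before normalization; renormalization
then uses the area of the positive part, with negative bins retained.

## Sigma surge at NREMS→REMS transitions

Transitions require ≥ 5 NREMS epochs (MA counting as NREMS) followed by
≥ 5 REMS epochs.  The relative sigma trace (percent of the recording's
mean full-band power) is lowpass-filtered, windows of [−200, +60] s
around each first REMS epoch are averaged pointwise (offsets with no
data are excluded, not padded), and the average is PCHIP-upsampled to
10 Hz.  Epoch values are attributed to epoch midpoints — an epoch's
power summarizes [t, t+4) — which halves the worst-case peak
quantization error.  The highest peak within the final 50 s of NREMS
gives the surge amplitude; latency is the time from that peak to REMS
entry.  Peak detection runs on the per-recording averaged trace only,
not per transition.

## Closed-loop stimulation

The simulator replays the online rule at epoch resolution: trigger when
slow (0.5–1 Hz) and sigma (10–15 Hz) relative power both exceed their
thresholds (AND predicate; OR is selectable) and at least
train + gap = 100 s have elapsed since the previous onset.  Trains last
50 s; pulse-level structure (10 Hz) is metadata.  A one-epoch detection
latency mirrors real-time epoch-wise processing; a sustain length > 1
epoch is configurable but defaults to single-epoch triggering.  The
detector sees only the power series — the hypnogram and ISO phase enter
exclusively through evaluation (trigger specificity, phase statistics).

Calibration grid-searches percentile-derived threshold pairs,
discarding pairs with < 95% of onsets in true-NREMS epochs or fewer than
5 triggers, and maximizes the mean circular alignment of onset ISO
phases with the ISO peak.  When no ground-truth phase is supplied the
phase is estimated from the filtered sigma trace via the analytic
signal.  Calibration is fully deterministic.

## Synthetic recordings

The generator emulates a light-phase mouse recording (default 3 h):

* **Vigilance chain** — semi-Markov over W/N/R with geometric epoch
  dwell times (means: wake 60 s, NREMS 160 s, REMS 60 s; NREMS→REMS
  probability 0.25; REMS exits to wake).  Geometric dwells are the
  simplest memoryless choice adequate for structure recovery.  Wake
  runs entered from NREMS have a 4-epoch minimum so that no
  chain-generated wake run can accidentally satisfy the MA rule — the
  ground-truth MA list therefore equals the detector output exactly.
* **ISO phase** — an accumulator advancing 2π·4/T per NREMS epoch
  (T = 50 s default), frozen during brief interruptions and reset after
  wake longer than 60 s; sigma on NREMS epochs is
  baseline · (1 + A sin φ) with A = 0.4.
* **Microarousals** — the event count is Poisson at 12 events per hour
  of NREMS; onsets are drawn by weighted sampling over rule-compatible
  epochs with a von Mises weight (κ = 2) centered on the ISO trough
  (φ = −π/2), rejecting placements that leave < 16 s of NREMS between
  events.  Rule-spacing conflicts shave a few percent off the nominal
  rate at concentrated phase preference; the realized rate stays within
  sampling error of nominal.  κ is a free parameter: the strength of
  the phase preference is qualitative in vivo, not quantified.
* **Band powers** — state-dependent baselines, delta elevated early in
  NREMS bouts (60-s decay), slow/delta declining and sigma ramping to a
  surge (amplitude 0.5 × baseline over 32 s) before REMS entry, a
  wake/MA EMG-like broadband floor, Gaussian noise per band.  The full
  band is the sum of named bands plus a non-negative floor, so
  mean(full) ≥ Σ band means by construction.  The pre-REMS slow/delta
  decline mirrors the documented loss of slow-wave activity approaching
  REMS and is what allows calibrated closed-loop thresholds to avoid
  triggering into REMS despite the sigma surge.
* **Photometry** — F(t) = bleach(t) · F0 · (1 + artifact + a sin(φ+π) ·
  1[NREMS] + noise) at 20 Hz, with a degree-2 polynomial bleach
  (≈ −20% over 3 h), fluorescence drops of 10%/15% in wake/REMS,
  CRH amplitude a = 0.05 ΔF/F and white noise (SD 0.003).  The "mut"
  control keeps everything but the CRH term, with an identical noise
  stream under the same seed.  F0 is arbitrary — magnitudes cancel in
  ΔF/F.

All randomness derives from a single seed through spawned substreams;
identical parameters give bit-identical outputs.

**What passing tests show — and don't.**  The generator's artifacts are
piecewise-constant per state, its noise is white, the ISO is a pure
sinusoid in phase, and no EEG/EMG waveforms are synthesized.  Passing
tests therefore demonstrate the correctness of the algorithms and the
recoverability of the encoded structure, not robustness to colored
noise, gradual state transitions, sensor saturation, movement artifacts
or scoring disagreement in real data.

## Numerical choices

Linear interpolation for downsampling matches the stated 1-D default;
the 1-s envelope is a monotone interpolant (no overshoot), flagged as
one of two readings of "envelope".  Cross-correlation ties resolve to
the lag nearest zero.  Degenerate inputs fail loudly: zero NREMS SD,
non-positive bleaching fit, constant PSD after baseline subtraction,
segments of the wrong length, unknown scores (with line numbers in file
readers).  Missing results are reported as missing (NaN/absent), never
as zero.

## Problem sizes

Defaults were chosen so a full synthetic recording is statistically
useful yet cheap: 3 h = 2700 epochs yields ~6–10 consolidated
NREMS bouts > 300 s, ~15–20 peak-to-peak segments, ~5–10 REMS
transitions and ~60–80 closed-loop triggers per recording.  Monte-Carlo
assertions in the tests use 20–200 seeded replicates depending on the
statistic.
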