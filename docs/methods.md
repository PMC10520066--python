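# Methods

This note documents the models, numerical choices and limitations behind
`somnohrv`.  All constants below are the package defaults in
`RunConfig` / `SimConfig`; everything stated as a measured number is
computed by the test suite or `scripts/acceptance.py`.

## Spectral primitive

All spectra — EEG, EMG and RR alike — come from one primitive
(`spectral.sliding_spectrum`): 16-s windows with an 8-s hop (50% overlap),
per-window mean removal, Hamming taper, and an FFT periodogram normalized so
that the summed one-sided bin power equals the taper-corrected variance
Σ(w·x̃)² / Σw² of the window (an exact Parseval identity, asserted to 1e-6
relative in the tests).  Under this normalization a unit-amplitude sinusoid
contributes ≈ A²/2 = 0.5 summed over its spectral line, which is what makes
band powers directly interpretable as signal variance in ms² (HRV) or µV²
(EEG/EMG).  Frequency resolution is 1/16 Hz.  Band edges are half-open
[low, high): the bin at exactly 4 Hz belongs to θ, and the LF/HF boundary
bin at 0.6 Hz belongs to HF (with 1/16 Hz resolution no bin falls at
0.06 Hz).  Per-window periodograms are used rather than Welch averaging
because the staging needs *per-epoch* features.

Epoch mapping: epoch *k* (8 s) takes the features of the window starting at
8·k s, i.e. the window covering this epoch and the next; the trailing epoch
without a full window is dropped.  The window therefore blends information
across one epoch boundary — the dominant source of staging error at stage
transitions (see Limitations).

## Staging

MPF is the power-weighted mean frequency over 1–32 Hz — the union of the
four scored EEG bands, inside the 0.16–48 Hz acquisition passband.  EMG
"power magnitude" is band power (not amplitude) over the 34–103 Hz
passband; only the data-driven threshold placement would change under the
amplitude convention.

Thresholds are estimated per 5-h segment (a final partial segment ≥ 30 min
gets its own thresholds, shorter tails reuse the previous segment's; a
recording must cover ≥ 30 min).  Each histogram (MPF; log₁₀ EMG power) is
split by 1-D Otsu on a 128-bin histogram.  Otsu replaces the manual
fine-tuning an experienced rater would perform; manual overrides are
accepted and recorded in provenance.  Because the Otsu objective is nearly
flat across a wide inter-mode gap, correctness is tested by achieved
between-class variance against an exhaustive-split oracle, not by threshold
location.  As a unimodality alarm the Sarle bimodality coefficient
(skew² + 1)/kurtosis is computed per histogram; values below 0.5 (a
Gaussian scores ≈ 0.33) flag the segment and emit a warning.  Boundary
convention: "above" is strict (>), "below" non-strict (≤); ties on
continuous features are measure-zero.

Interruption-rate normalization: the default `interruption_rate` divides
all sub-6-epoch runs by total valid minutes; `qs_interruption_rate` is the
stricter phenotype-oriented variant counting only events flanked by QS on
both sides per minute of QS.  Both are reported.  Transitions are counted
between consecutive formed bouts (interruption runs are skipped), since
transitions are defined over stages and stages require bout formation.

## HRV chain

R-peak detection is the Pan–Tompkins recipe scaled to rat heart rates
(~300 bpm): 5–40 Hz band-pass, squaring, 60-ms moving-window integration,
peaks above 0.2× the 99th percentile of the integrated signal with a 60-ms
refractory distance, each refined to the local maximum of the raw trace
within ±40 ms.  Refinement runs on a copy smoothed with an 18-ms Hann
kernel: without it, sample-level noise shifts the apex by ±1 sample at
realistic SNR.

The tachogram assigns interval RRᵢ to the time of its *ending* beat.
Artifact masking: intervals outside 100–350 ms, or deviating > 30% from the
centered rolling median of 9 intervals.  Masked intervals are excluded from
the spline support and thereby bridged.  Resampling is a cubic spline
(`CubicSpline`) on a uniform 64-Hz grid from the first to last usable beat;
cubic rather than linear because linear interpolation adds broadband
harmonic leakage to the 64-Hz series.

Stage conditioning: a 16-s RR segment gets a stage only when *every* epoch
it overlaps carries the same non-ERR label (`rule="both"`); a majority-vote
variant is available.  Aggregation applies the natural log to the
per-recording *mean* band power per stage (`log_of_mean`, default) rather
than averaging per-segment logs; both orders are exposed.  The natural log
is used throughout: on that scale the reported LF/HF equals
log LF − log HF exactly (asserted exactly in every output row), and
e-scaled powers (HF ≈ 4.5 ms², LF ≈ 11 ms²) are physiologic for rat.
Stages with no assigned segments are reported absent, not zero.

## Group statistics

Normality gate: Shapiro–Wilk per group at α = 0.05 (the gate level is a
package choice).  Equal-variance pooled Student t (not Welch) — the pooled
form is what reproduces published p-values from printed mean ± SD summaries
(`pooled_t_from_summary`).  Mann–Whitney is exact for n ≤ 8 per group
without ties (verified against full C(12,6) = 924 enumeration), otherwise
normal approximation with tie correction.  p-values are also rounded to
3 decimals in reports, the precision customary in print.  No
multiple-testing correction is applied — deliberately, matching common
practice in small-cohort physiology reports; interpret row-wise p
accordingly.

## Synthetic-data generator

The generator's job is to produce signals whose *statistics* match what the
analysis assumes, with known ground truth.

**Hypnogram.** Bout lengths are 6-shifted geometric, 6 + Geom(mean − 6):
memoryless above the 6-epoch bout-formation floor, so every natural run
scores as a bout and sub-6-epoch runs are exactly the injected intrusions.
(A plain geometric would put ~25–40% of runs under the floor and the
"interruption rate" would be dominated by accidental churn, contradicting
the event rates the presets are meant to encode.)  The next stage is drawn
with probability ∝ occupancy deficit / mean bout length — a
negative-feedback rule that drives realized stage fractions to
`stage_mix`.  A stationary no-self-transition chain cannot enter any stage
more than half the time, which caps a stage's occupancy by its bout-length
ratio; bout means must be chosen jointly feasible with the mix.  Defaults:
control AW 8 / QS 24 / PS 18 epochs (64 s / 3.2 min / 2.4 min — brief wake
bouts, QS longest), exposure-like AW 8 / QS 40 / PS 12 (its 60% QS demands
longer QS bouts under the cap).  QS interruptions are injected per QS bout
as Poisson events at the configured rate per QS minute, each a 1–5-epoch
AW run placed with a 1-epoch QS margin so it never merges with a
neighboring run; the occupancy target is pre-compensated for the expected
QS→AW conversion (~0.4 × rate of QS time, AW floored at 0.5%).  For the
exposure preset the conversion exceeds its configured AW share, so the
compensation saturates and realized AW runs a few points above the mix —
presets mimic the phenotype directionally, not cell-by-cell.

**EEG.** Four band components (δ/θ/α/β edges above) are white noise
filtered with 4th-order Butterworth band-passes (applied forward-backward),
each normalized to unit power *inside its own band*, then mixed per epoch
with gains √(weight) from the stage's normalized band weights.  Gains are
cross-faded with a 0.5-s Hann kernel at stage changes to keep the trace
continuous.  Filter transition bands leak a few percent across edges:
configured fractions are recovered within ±0.03 at 30 min.

**EMG.** One 34–103 Hz component with per-epoch RMS `emg_gain[stage]`
(defaults 10 / 1 / 0.5 for AW / QS / PS — waking muscle tone, sleep
hypotonia, PS atonia), same cross-fade.

**ECG.** Integral pulse frequency modulation: instantaneous
RR(t) = mean_rr + lf_amp(stage)·sin(2π·0.3·t) + hf_amp(stage)·sin(2π·1.2·t)
+ noise, with noise a < 2 Hz Gaussian process of SD `rr_noise_sd`
(default 0.5 ms, kept small so band powers are modulation-dominated).  A
beat fires when ∫1/RR crosses an integer (crossing times linearly
interpolated on the 1/500-s grid); each beat renders a 40-ms raised-cosine
spike of unit amplitude — sufficient for R-detection, no P/T waves.
Default mean RR 200 ms (≈ 300 bpm).  Modulation amplitudes are set so that
sinusoid variance A²/2 reproduces control-like log band powers per stage
(e.g. QS: ln(4.10²/2) = 2.13 for LF, ln(2.98²/2) = 1.49 for HF, hence
log LF/HF 0.64); the exposure preset raises QS log LF/HF by +0.52.

Seeding: one global seed spawns fixed per-channel child streams
(`default_rng([seed, k])` with k = 0..3 for labels/EEG/EMG/ECG), so
channels are independent but jointly reproducible; identical (config, seed)
yields identical output everywhere.

**Known attenuation.** Sampling a continuous modulation at beat intervals
low-pass filters it by ≈ sinc²(f·RR): at 1.2 Hz with RR 0.2 s the HF power
recovered through the full beat chain is ~0.82 of A²/2, while LF at 0.3 Hz
is essentially unattenuated.  Consequently pipeline log LF/HF runs
~+0.1–0.2 above the configured value in every arm; contrasts between arms
are preserved.  Band-power recovery against the A²/2 target is therefore
validated on directly constructed RR series, and the beat chain is
validated for quadratic amplitude scaling and for group contrasts.

**What the generator does not emulate** — and hence what passing tests do
not establish about real recordings: electrode artifacts and baseline
drift, real QRS morphology and ectopy, circadian/ultradian drift within a
session, respiratory-frequency wander in HF, EEG spindles/transients, and
multi-day session structure (the generator produces single continuous
sessions; stitching is the caller's concern).  ERR epochs essentially never
arise from synthetic data (low MPF with high EMG is excluded by
construction), so the ERR pathway is exercised by unit tests, not by the
generator.

## Problem sizes in the validation harness

The acceptance harness uses: a 30-min control recording for staging
accuracy (≥ 90% against ground truth); 20 cohort replicates (6 + 6 animals,
20-min signals, ground-truth beats and labels) for null calibration and
power of the QS log LF/HF comparison; and 20 end-to-end cohort replicates
(6 + 6 animals, 60-min recordings through the full EDF-free pipeline) for
the directional exposure contrast.  Sixty-minute recordings are used for
the directional check because the per-animal QS interruption rate is
Poisson-noisy at 30 min (SD ≈ 0.19/min vs ≈ 0.15/min at 60 min); cohort
averaging over 6 animals then separates the arms cleanly.

## Degenerate inputs and numerical edges

Constant features → degenerate-histogram warning and zero-width threshold;
all-masked tachogram → warning, downstream resampling refuses (< 2 usable
intervals); zero in-band power → explicit error for MPF/fractions; both
group SDs zero with equal means → p = 1 by convention; empty stages →
absent rows, never fabricated zeros.  EDF output quantizes to 16 bits over
each channel's observed range (round-trip error ≤ one quantization step,
verified also against an independent EDF reader); the NPZ container is
bit-exact.

## Limitations

* Staging accuracy is bounded by the 16-s window blending at stage
  boundaries; 1-epoch intrusions typically smear to ~2 epochs.  Measured
  interruption rates therefore run slightly above the injected ground-truth
  rates, consistently across arms.
* Otsu thresholding assumes each histogram is effectively two-population
  within a 5-h segment; pathological mixtures (e.g. a segment of pure QS)
  flag as unimodal but still produce a split.
* The two-state-mix generator configuration cannot reach an arbitrary stage
  mix (occupancy is fixed by bout-length ratio when only two stages
  alternate); three-state mixes are reachable up to the occupancy cap.
* No time-domain (SDNN/RMSSD) or nonlinear HRV indices; no human (AASM)
  staging conventions.
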