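# somnohrv

Sleep staging and stage-conditioned spectral heart-rate variability (HRV)
for rodent polysomnography.

Chronic telemetry studies in rats record EEG, nuchal EMG, and ECG around an
intervention (drug, toxin, aerosol exposure) and ask two questions: *how did
sleep architecture change* (stage fractions, bout durations, fragmentation)
and *how did cardiac autonomic balance change within each sleep stage*
(spectral HRV).  `somnohrv` implements that analysis chain as a tested,
reusable library with a CLI, plus a seeded synthetic-signal generator so the
whole chain can be validated against known ground truth without animal data.

## The method

**Staging.** EEG (125 Hz) and EMG (250 Hz) are analyzed in 16-s Hamming
windows with 50% overlap, giving per-8-s-epoch features: the EEG **mean
power frequency** MPF = Σf·P(f)/ΣP(f) over 1–32 Hz, and the EMG band power
over its 34–103 Hz passband.  Per 5-h segment, the MPF histogram separates
the active-waking/paradoxical-sleep complex from quiet sleep, and the
log-EMG-power histogram separates active waking from sleep; each is split
automatically at the 1-D Otsu point (maximal between-class variance), with
manual override supported.  Epochs classify as

| MPF > T_MPF | EMG > T_EMG | stage |
|---|---|---|
| yes | yes | AW (active waking) |
| no  | no  | QS (quiet sleep) |
| yes | no  | PS (paradoxical sleep) |
| no  | yes | ERR (excluded) |

Runs of ≥ 6 identical epochs form stage bouts; shorter runs are
**interruption events** (sleep fragmentation).  Architecture metrics: stage
time %, mean bout duration, interruption rate (events/min), the six bout
transition counts (A–Q, A–P, Q–A, Q–P, P–A, P–Q), and the QS EEG band
profile in normalized units (δ 1–4, θ 4–8, α 8–13, β 13–32 Hz).

**HRV.** R peaks are detected from 500-Hz ECG (band-pass, square,
integrate, adaptive threshold), the RR tachogram is artifact-masked, cubic
interpolated and resampled at 64 Hz, then analyzed in 1024-point (16-s)
Hamming-FFT segments with 50% overlap.  Band powers (rat bands) are
LF = Σ P(f), f ∈ [0.06, 0.6) Hz and HF = Σ P(f), f ∈ [0.6, 2.4] Hz, in ms².
A segment inherits a sleep stage when every epoch it overlaps agrees.  Per
stage, powers are natural-log transformed and the sympathovagal index is
reported as log LF/HF = log LF − log HF (an exact identity in every output
row).

**Statistics.** Two-group comparison per metric: Shapiro–Wilk per group at
α = 0.05; if both pass, an equal-variance (pooled) Student t-test, else a
two-tailed Mann–Whitney U (exact for n ≤ 8 per group).  Groups are reported
as mean ± sample SD.  `pooled_t_from_summary` recomputes t and p directly
from printed mean/SD/n table cells.

**Synthetic data.** `SimConfig` describes a virtual animal: a semi-Markov
AW/QS/PS hypnogram with 6-shifted geometric bouts and Poisson-injected
short AW intrusions into QS; EEG as stage-weighted band-limited noise; EMG
as 34–103 Hz noise with stage-dependent RMS; ECG beats from an
integral-pulse-frequency-modulation model whose instantaneous RR carries
stage-dependent LF and HF sinusoidal modulation.  `control_preset()` and
`pm25_preset()` encode a control-like and an exposure-like phenotype (more
fragmented QS, higher QS LF/HF).

## Worked example

```sh
somnohrv simulate --preset control --seed 3 --duration-min 35 --out sim
somnohrv report sim/recording.edf --out results
```

prints the stage-conditioned HRV summary:

```
         n_segments  mean_rr_ms    log_lf    log_hf  log_lfhf
stage
overall         260  199.981060  2.539835  1.444483  1.095352
AW               22  199.981380  2.587407  1.376405  1.211002
QS               95  199.986251  2.145760  1.423444  0.722316
PS               93  199.974839  2.840545  1.488666  1.351879
```

Each row gives the number of 16-s RR segments assigned to the stage, the
mean RR interval (ms), natural-log LF and HF power (ms² before the log),
and their difference, the log LF/HF balance.  Here QS shows the lowest
LF/HF (vagal dominance in deep sleep, log LF/HF ≈ 0.72) while AW and PS
run sympathetically higher — the control-like pattern the generator encodes.
`results/` also receives `features.csv`, `hypnogram.csv`, `bouts.csv`,
`architecture.csv`, and `hrv_segments.csv`, each stamped with the analysis
config hash.  Per-animal metrics from several runs can then be compared with
`somnohrv compare metrics.csv --out report.csv`.

Equivalent library calls:

```python
import somnohrv as sh

sim = sh.generate_recording(sh.control_preset(), seed=3)
bundle = sh.run_pipeline(sim.recording)
print(bundle["architecture"].time_pct, bundle["stage_hrv"])
```

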