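"""Seeded synthetic rodent EEG/EMG/ECG with ground-truth hypnogram and beats.

The generator emulates the statistical structure the analysis chain assumes:

* a three-state hypnogram (AW / QS / PS) built as a semi-Markov chain with
  geometric (memoryless) bout lengths, plus short AW intrusions injected into
  QS bouts as a Poisson process — the "QS interruption" phenotype;
* EEG as a stage-weighted sum of band-limited Gaussian noise in the four
  classical rodent bands delta (1-4 Hz), theta (4-8), alpha (8-13),
  beta (13-32);
* EMG as 34-103 Hz band-limited noise whose RMS follows the stage
  (high in active waking, low in sleep, lowest in paradoxical sleep atonia);
* ECG beats from an integral-pulse-frequency-modulation (IPFM) model whose
  instantaneous RR carries stage-dependent sinusoidal LF and HF modulation,
  rendered as a raised-cosine QRS spike train at 500 Hz.

One global seed expands to fixed per-channel child streams, so channels are
independent but jointly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import signal

from .io import CHANNEL_RATES, Recording, ValidationError

STAGES: Tuple[str, ...] = ("AW", "QS", "PS")
BAND_NAMES: Tuple[str, ...] = ("delta", "theta", "alpha", "beta")
BAND_EDGES: Dict[str, Tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 32.0),
}
EMG_BAND: Tuple[float, float] = (34.0, 103.0)

# Fixed per-channel child-stream offsets under the global seed.
_STREAM = {"labels": 0, "eeg": 1, "emg": 2, "ecg": 3}


class SimConfig(BaseModel):
    """Generator configuration; defaults describe a control-like animal.

    ``stage_mix`` is the target long-run fraction of time per stage,
    ``stage_mean_bouts`` the mean bout length in 8-s epochs,
    ``qs_interruption_rate`` the rate (events per minute of QS) of short AW
    intrusions injected into QS bouts.  RR modulation amplitudes are in ms at
    ``lf_mod_freq`` / ``hf_mod_freq`` (Hz); the LF sinusoid must live in
    0.06-0.6 Hz and the HF one in 0.6-2.4 Hz.
    """

    epoch_len: float = 8.0
    duration_min: float = 30.0
    stage_mix: Dict[str, float] = Field(
        default_factory=lambda: {"AW": 0.108, "QS": 0.478, "PS": 0.414}
    )
    stage_mean_bouts: Dict[str, float] = Field(
        default_factory=lambda: {"AW": 8.0, "QS": 24.0, "PS": 18.0}
    )
    qs_interruption_rate: float = 0.35
    eeg_band_weights: Dict[str, Tuple[float, float, float, float]] = Field(
        default_factory=lambda: {
            "AW": (0.15, 0.35, 0.25, 0.25),
            "QS": (0.88, 0.068, 0.025, 0.027),
            "PS": (0.20, 0.50, 0.15, 0.15),
        }
    )
    emg_gain: Dict[str, float] = Field(
        default_factory=lambda: {"AW": 10.0, "QS": 1.0, "PS": 0.5}
    )
    mean_rr: float = 200.0
    lf_mod_freq: float = 0.3
    hf_mod_freq: float = 1.2
    # Amplitudes chosen so sinusoid band powers A^2/2 reproduce control-like
    # log-scale LF/HF per stage (e.g. QS: ln(4.1^2/2)=2.13, ln(3.0^2/2)=1.49).
    rr_lf_amp: Dict[str, float] = Field(
        default_factory=lambda: {"AW": 5.19, "QS": 4.10, "PS": 5.85}
    )
    rr_hf_amp: Dict[str, float] = Field(
        default_factory=lambda: {"AW": 2.95, "QS": 2.98, "PS": 3.13}
    )
    rr_noise_sd: float = 0.5
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        mix = self.stage_mix
        if any(v < 0 for v in mix.values()):
            raise ValueError("stage_mix components must be non-negative")
        if abs(sum(mix.values()) - 1.0) > 1e-6:
            raise ValueError("stage_mix must sum to 1")
        if any(m <= 6 for m in self.stage_mean_bouts.values()):
            raise ValueError(
                "mean bout lengths must exceed the 6-epoch bout floor"
            )
        if not (0.06 <= self.lf_mod_freq < 0.6):
            raise ValueError("lf_mod_freq must lie in [0.06, 0.6)")
        if not (0.6 <= self.hf_mod_freq <= 2.4):
            raise ValueError("hf_mod_freq must lie in [0.6, 2.4]")
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        for amps in (self.rr_lf_amp, self.rr_hf_amp, self.emg_gain):
            if any(a < 0 for a in amps.values()):
                raise ValueError("amplitudes must be non-negative")
        if self.qs_interruption_rate < 0 or self.rr_noise_sd < 0:
            raise ValueError("rates and noise SD must be non-negative")
        return self

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_min * 60.0 / self.epoch_len))


def control_preset(**overrides) -> SimConfig:
    """Control-like animal: defaults as documented on SimConfig."""
    return SimConfig(**overrides)


def pm25_preset(**overrides) -> SimConfig:
    """Exposed-like animal: more fragmented QS and sympathetic-shifted HRV.

    Relative to the control preset: higher QS fraction with a higher QS
    interruption rate, slightly delta-shifted QS EEG, and larger LF (and for
    AW/PS also HF) RR modulation, raising log LF/HF in every stage and most
    strongly in QS (+0.52 on the natural-log scale).
    """
    params = dict(
        stage_mix={"AW": 0.113, "QS": 0.603, "PS": 0.284},
        # more QS time requires longer QS bouts (a stage cannot follow
        # itself, so occupancy is capped by bout-length ratios)
        stage_mean_bouts={"AW": 8.0, "QS": 40.0, "PS": 12.0},
        qs_interruption_rate=0.52,
        eeg_band_weights={
            "AW": (0.15, 0.35, 0.25, 0.25),
            "QS": (0.828, 0.092, 0.037, 0.043),
            "PS": (0.20, 0.50, 0.15, 0.15),
        },
        rr_lf_amp={"AW": 7.70, "QS": 5.37, "PS": 7.51},
        rr_hf_amp={"AW": 3.64, "QS": 3.01, "PS": 3.38},
    )
    params.update(overrides)
    return SimConfig(**params)


@dataclass
class GroundTruth:
    """Oracle labels for recovery tests: the injected hypnogram and beats."""

    epoch_labels: np.ndarray  # '<U3', one of AW/QS/PS per epoch
    beat_times: np.ndarray  # seconds, strictly increasing
    injected_interruptions: List[Tuple[int, int]]  # (start_epoch, n_epochs)


@dataclass
class SimRecording:
    recording: Recording
    truth: GroundTruth
    config: SimConfig


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stream]])


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------

def simulate_stage_sequence(config: SimConfig, seed: int | None = None) -> GroundTruth:
    """Semi-Markov AW/QS/PS sequence with injected QS interruptions.

    Bout lengths are 6-shifted geometric at the configured per-stage means
    (memoryless above the 6-epoch bout-formation floor, so every natural run
    scores as a bout and short runs are exactly the injected intrusions).
    The next stage is drawn with probability proportional to its remaining
    occupancy deficit divided by its mean bout length, a negative-feedback
    rule that drives realized stage fractions to ``stage_mix``.  Short (1-5
    epoch) AW runs are then injected inside QS bouts as a Poisson process at
    ``qs_interruption_rate`` per minute of QS; the occupancy target is
    pre-compensated for the expected QS->AW conversion.  Returns a
    GroundTruth with empty ``beat_times``.
    """
    rng = _rng(config.seed if seed is None else seed, "labels")
    n = config.n_epochs
    mix = {s: config.stage_mix.get(s, 0.0) for s in STAGES}
    target = _injection_compensated_mix(config, mix)

    active = [s for s in STAGES if target[s] > 0]
    if not active:
        raise ValidationError("stage_mix has no positive component")
    labels = np.empty(n, dtype="<U3")
    if len(active) == 1:
        labels[:] = active[0]
    else:
        tgt = np.array([target[s] for s in active])
        tgt /= tgt.sum()
        means = np.array([config.stage_mean_bouts[s] for s in active])
        counts = np.zeros(len(active))
        cur = int(rng.choice(len(active), p=tgt))
        filled = 0
        while filled < n:
            p = min(1.0 / (means[cur] - 6.0), 1.0)
            bout = 6 + int(rng.geometric(p))
            labels[filled : filled + bout] = active[cur]
            counts[cur] += min(bout, n - filled)
            filled += bout
            # occupancy-deficit feedback: favor stages lagging their target,
            # discounting stages with long bouts (they catch up per entry)
            deficit = np.maximum(tgt - counts / max(filled, 1), 1e-3 * tgt)
            w = deficit / means
            w[cur] = 0.0
            cur = int(rng.choice(len(active), p=w / w.sum()))

    injected: List[Tuple[int, int]] = []
    if config.qs_interruption_rate > 0 and "QS" in active:
        for start, length in _runs(labels):
            if labels[start] != "QS":
                continue
            minutes = length * config.epoch_len / 60.0
            n_ev = rng.poisson(config.qs_interruption_rate * minutes)
            occupied = np.zeros(length, dtype=bool)
            for _ in range(n_ev):
                k = int(rng.integers(1, 6))
                # interior placement with a 1-epoch QS margin on both sides,
                # so the intrusion is flanked by QS and never merges
                lo, hi = 1, length - 1 - k
                if hi < lo:
                    continue
                for _attempt in range(50):
                    pos = int(rng.integers(lo, hi + 1))
                    if not occupied[pos - 1 : pos + k + 1].any():
                        labels[start + pos : start + pos + k] = "AW"
                        occupied[pos - 1 : pos + k + 1] = True
                        injected.append((start + pos, k))
                        break
    injected.sort()
    return GroundTruth(
        epoch_labels=labels, beat_times=np.empty(0), injected_interruptions=injected
    )


def _injection_compensated_mix(
    config: SimConfig, mix: Dict[str, float]
) -> Dict[str, float]:
    """Pre-injection occupancy target compensating the QS->AW conversion.

    A rate r per QS minute with mean intrusion length 3 epochs converts
    ~0.4*r of QS time to AW, so the pre-injection target inflates QS and
    deflates AW accordingly (AW floored at 0.5%; when the configured rate
    converts more AW-time than the mix allots, the compensated target
    saturates and realized fractions deviate from the configured mix).
    """
    phi = min(0.4 * config.qs_interruption_rate * config.epoch_len / 8.0, 0.9)
    if mix["QS"] <= 0 or phi <= 0:
        return dict(mix)
    comp = dict(mix)
    moved = mix["QS"] * phi / (1.0 - phi)
    comp["QS"] = mix["QS"] / (1.0 - phi)
    comp["AW"] = max(mix["AW"] - moved, 0.005 if mix["AW"] > 0 else 0.0)
    total = sum(comp.values())
    return {s: v / total for s, v in comp.items()}


def _runs(labels: np.ndarray):
    """Yield (start, length) of maximal constant runs."""
    n = len(labels)
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            yield start, i - start
            start = i


# ---------------------------------------------------------------------------
# EEG / EMG
# ---------------------------------------------------------------------------

def _band_noise(rng, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Band-limited Gaussian noise with unit power inside [lo, hi)."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    f, p = signal.periodogram(x, fs)
    inband = p[(f >= lo) & (f < hi)].sum() * (f[1] - f[0])
    return x / np.sqrt(inband) if inband > 0 else x


def _smooth_envelope(per_epoch: np.ndarray, spe: int, fs: float) -> np.ndarray:
    """Per-sample envelope from per-epoch values, cross-faded over <=0.5 s."""
    env = np.repeat(per_epoch, spe)
    k = int(round(0.5 * fs))
    if k > 1 and np.ptp(per_epoch) > 0:
        kern = np.hanning(k)
        kern /= kern.sum()
        smoothed = signal.oaconvolve(env, kern, mode="same")
        # undo edge shrinkage from 'same' convolution
        norm = signal.oaconvolve(np.ones_like(env), kern, mode="same")
        env = smoothed / norm
    return env


def synthesize_eeg(
    labels: np.ndarray, config: SimConfig, seed: int | None = None
) -> np.ndarray:
    """EEG at 125 Hz: stage-weighted sum of four band-noise components.

    Per epoch the component powers are proportional to the stage's band
    weights (normalized to unit total), with raised-cosine cross-fades at
    stage changes so the trace is continuous.
    """
    if len(labels) == 0:
        raise ValidationError("labels must be non-empty")
    unknown = set(np.unique(labels)) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stage labels: {sorted(unknown)}")
    fs = CHANNEL_RATES["eeg"]
    rng = _rng(config.seed if seed is None else seed, "eeg")
    spe = int(round(config.epoch_len * fs))
    n = len(labels) * spe

    weights = {}
    for s, w in config.eeg_band_weights.items():
        w = np.asarray(w, dtype=float)
        if w.sum() <= 0:
            raise ValidationError(f"band weights for {s} must have positive sum")
        weights[s] = w / w.sum()

    out = np.zeros(n)
    for bi, name in enumerate(BAND_NAMES):
        comp = _band_noise(rng, n, fs, *BAND_EDGES[name])
        gains = np.array([np.sqrt(weights[s][bi]) for s in labels])
        out += _smooth_envelope(gains, spe, fs) * comp
    return out


def synthesize_emg(
    labels: np.ndarray, config: SimConfig, seed: int | None = None
) -> np.ndarray:
    """EMG at 250 Hz: 34-103 Hz noise with stage-dependent RMS."""
    if len(labels) == 0:
        raise ValidationError("labels must be non-empty")
    unknown = set(np.unique(labels)) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stage labels: {sorted(unknown)}")
    fs = CHANNEL_RATES["emg"]
    rng = _rng(config.seed if seed is None else seed, "emg")
    spe = int(round(config.epoch_len * fs))
    n = len(labels) * spe
    comp = signal.sosfiltfilt(
        signal.butter(4, EMG_BAND, btype="bandpass", fs=fs, output="sos"),
        rng.standard_normal(n),
    )
    std = comp.std()
    if std > 0:
        comp /= std
    gains = np.array([config.emg_gain[s] for s in labels], dtype=float)
    return _smooth_envelope(gains, spe, fs) * comp


# ---------------------------------------------------------------------------
# ECG (IPFM)
# ---------------------------------------------------------------------------

def synthesize_ecg(
    labels: np.ndarray, config: SimConfig, seed: int | None = None
) -> Tuple[np.ndarray, np.ndarray]:
    """ECG at 500 Hz plus ground-truth beat times from an IPFM model.

    Instantaneous RR(t) [ms] = mean_rr + lf_amp(stage)*sin(2*pi*f_lf*t)
    + hf_amp(stage)*sin(2*pi*f_hf*t) + band-limited noise; a beat fires each
    time the integral of the instantaneous rate 1/RR crosses an integer.
    Each beat is rendered as a 40-ms raised-cosine spike of unit amplitude
    (adequate for R-peak detection; no P/T waves).
    """
    if len(labels) == 0:
        raise ValidationError("labels must be non-empty")
    worst = max(
        config.rr_lf_amp.get(s, 0.0) + config.rr_hf_amp.get(s, 0.0)
        for s in np.unique(labels)
    )
    if worst >= config.mean_rr:
        raise ValidationError(
            "total modulation amplitude must be smaller than mean_rr "
            f"({worst} >= {config.mean_rr})"
        )
    fs = CHANNEL_RATES["ecg"]
    rng = _rng(config.seed if seed is None else seed, "ecg")
    spe = int(round(config.epoch_len * fs))
    n = len(labels) * spe
    dt = 1.0 / fs
    t = np.arange(n) * dt

    lf_amp = _smooth_envelope(
        np.array([config.rr_lf_amp[s] for s in labels], dtype=float), spe, fs
    )
    hf_amp = _smooth_envelope(
        np.array([config.rr_hf_amp[s] for s in labels], dtype=float), spe, fs
    )
    rr = (
        config.mean_rr
        + lf_amp * np.sin(2 * np.pi * config.lf_mod_freq * t)
        + hf_amp * np.sin(2 * np.pi * config.hf_mod_freq * t)
    )
    if config.rr_noise_sd > 0:
        noise = signal.sosfiltfilt(
            signal.butter(4, 2.0, btype="lowpass", fs=fs, output="sos"),
            rng.standard_normal(n),
        )
        rr = rr + noise / noise.std() * config.rr_noise_sd
    if rr.min() <= 0:
        raise ValidationError("instantaneous RR became non-positive")

    integ = np.cumsum(1000.0 / rr) * dt  # beats; rate in beats/s
    ks = np.arange(1, int(np.floor(integ[-1])) + 1)
    pos = np.searchsorted(integ, ks)
    prev = np.where(pos > 0, integ[pos - 1], 0.0)
    t_prev = np.where(pos > 0, t[pos - 1], -dt)
    beat_times = t_prev + (ks - prev) / (integ[pos] - prev) * dt

    trace = np.zeros(n)
    half = int(round(0.020 * fs))  # 40 ms template
    template = np.hanning(2 * half + 1)
    centers = np.round(beat_times * fs).astype(int)
    for c in centers:
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        trace[lo:hi] += template[lo - (c - half) : hi - (c - half)]
    return trace, beat_times


def generate_recording(config: SimConfig, seed: int | None = None) -> SimRecording:
    """Bundle hypnogram + three traces + ground truth; deterministic per seed."""
    seed = config.seed if seed is None else seed
    truth = simulate_stage_sequence(config, seed)
    eeg = synthesize_eeg(truth.epoch_labels, config, seed)
    emg = synthesize_emg(truth.epoch_labels, config, seed)
    ecg, beats = synthesize_ecg(truth.epoch_labels, config, seed)
    truth.beat_times = beats
    rec = Recording(
        channels={"eeg": eeg, "emg": emg, "ecg": ecg},
        fs=dict(CHANNEL_RATES),
        provenance={"source": "synthetic", "seed": int(seed)},
    )
    return SimRecording(recording=rec, truth=truth, config=config)


def write_ground_truth(sim: SimRecording, labels_path, beats_path) -> None:
    """Sidecar CSVs: (epoch_index,label) and (beat_time_s)."""
    import pandas as pd

    pd.DataFrame(
        {
            "epoch_index": np.arange(len(sim.truth.epoch_labels)),
            "label": sim.truth.epoch_labels,
        }
    ).to_csv(labels_path, index=False)
    pd.DataFrame({"beat_time_s": sim.truth.beat_times}).to_csv(
        beats_path, index=False
    )
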