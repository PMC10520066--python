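"""Sliding Hamming-window spectra and per-epoch EEG/EMG features.

Every spectral quantity in the pipeline (EEG staging features and RR
spectra alike) comes from the same primitive: 16-s windows with 50% overlap
(8-s hop), mean removal, Hamming taper, and a periodogram normalized so that
the summed bin power equals the taper-corrected variance of the window
(exact Parseval identity).  At 16 s the frequency resolution is 1/16 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .io import DataError, ValidationError

EEG_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 32.0),
}
MPF_BAND = (1.0, 32.0)
EMG_BAND = (34.0, 103.0)

FEATURE_COLUMNS = [
    "epoch_index",
    "t_start_s",
    "mpf_hz",
    "emg_power",
    "delta_fr",
    "theta_fr",
    "alpha_fr",
    "beta_fr",
]


@dataclass
class Spectrogram:
    """Windowed power spectra: ``power[i, k]`` is bin power (signal units
    squared) of the window starting at ``times[i]`` at frequency ``freqs[k]``."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def sliding_spectrum(
    trace: np.ndarray, fs: float, window_s: float = 16.0, hop_s: float = 8.0
) -> Spectrogram:
    """Hamming-tapered periodogram per 16-s window, 8-s hop.

    Bin powers are normalized so their sum equals sum((w*x)^2)/sum(w^2) for
    each demeaned window — i.e. total power ~ window variance, and a unit
    sinusoid contributes ~0.5 at its line.
    """
    x = np.asarray(trace, dtype=float)
    n = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if len(x) < n:
        raise DataError(
            f"trace shorter than one window ({len(x)} < {n} samples)"
        )
    nwin = (len(x) - n) // hop + 1
    w = np.hamming(n)
    idx = np.arange(n)[None, :] + hop * np.arange(nwin)[:, None]
    seg = x[idx]
    seg = seg - seg.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(seg * w, axis=1)
    power = np.abs(spec) ** 2
    power[:, 1:] *= 2.0
    if n % 2 == 0:
        power[:, -1] /= 2.0
    power /= n * (w ** 2).sum()
    return Spectrogram(
        times=hop_s * np.arange(nwin, dtype=float),
        freqs=np.fft.rfftfreq(n, 1.0 / fs),
        power=power,
    )


def _band_mask(freqs: np.ndarray, band: Tuple[float, float]) -> np.ndarray:
    # half-open [low, high): a bin at exactly 4 Hz belongs to theta
    return (freqs >= band[0]) & (freqs < band[1])


def mean_power_frequency(
    power_row: np.ndarray, freqs: np.ndarray, band: Tuple[float, float] = MPF_BAND
) -> float:
    """Power-weighted mean frequency sum(f*P)/sum(P) over ``band``."""
    if band[0] < freqs[0] or band[1] > freqs[-1] + (freqs[1] - freqs[0]):
        raise ValidationError(f"band {band} outside spectrum range")
    m = _band_mask(freqs, band)
    total = power_row[m].sum()
    if total <= 0:
        raise DataError("zero in-band power; MPF undefined")
    return float((power_row[m] * freqs[m]).sum() / total)


def band_power_fractions(
    power_row: np.ndarray, freqs: np.ndarray
) -> Tuple[float, float, float, float]:
    """(delta, theta, alpha, beta) fractions of total 1-32 Hz power."""
    total = power_row[_band_mask(freqs, MPF_BAND)].sum()
    if total <= 0:
        raise DataError("zero total 1-32 Hz power; fractions undefined")
    return tuple(
        float(power_row[_band_mask(freqs, EEG_BANDS[b])].sum() / total)
        for b in ("delta", "theta", "alpha", "beta")
    )


def emg_band_power(
    power_row: np.ndarray, freqs: np.ndarray, band: Tuple[float, float] = EMG_BAND
) -> float:
    """Summed power in the EMG passband (34-103 Hz by default)."""
    if band[1] > freqs[-1] + (freqs[1] - freqs[0]):
        raise ValidationError(
            f"EMG band {band} exceeds spectrum Nyquist {freqs[-1]} Hz"
        )
    return float(power_row[_band_mask(freqs, band)].sum())


def epoch_features(
    eeg_spec: Spectrogram,
    emg_spec: Spectrogram,
    mpf_band: Tuple[float, float] = MPF_BAND,
    emg_band: Tuple[float, float] = EMG_BAND,
) -> pd.DataFrame:
    """Per-8-s-epoch features from aligned EEG and EMG spectrograms.

    Epoch k receives the features of the 16-s window starting at 8k s (the
    window covering this epoch and the next); the trailing epoch without a
    full window is dropped.  Columns: FEATURE_COLUMNS.
    """
    if len(eeg_spec.times) != len(emg_spec.times) or not np.allclose(
        eeg_spec.times, emg_spec.times
    ):
        raise DataError(
            "EEG and EMG spectrograms cover different time spans "
            f"({len(eeg_spec.times)} vs {len(emg_spec.times)} windows)"
        )
    rows = []
    for k in range(len(eeg_spec.times)):
        d, t, a, b = band_power_fractions(eeg_spec.power[k], eeg_spec.freqs)
        rows.append(
            (
                k,
                eeg_spec.times[k],
                mean_power_frequency(eeg_spec.power[k], eeg_spec.freqs, mpf_band),
                emg_band_power(emg_spec.power[k], emg_spec.freqs, emg_band),
                d,
                t,
                a,
                b,
            )
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)
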