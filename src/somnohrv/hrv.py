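"""Spectral heart-rate variability from rodent ECG.

Chain: R-peak detection (band-pass, square, integrate, adaptive threshold —
the Pan–Tompkins recipe scaled to rat heart rates) -> RR tachogram with
artifact masking -> cubic interpolation onto a uniform 64 Hz grid ->
16-s / 1024-point Hamming FFT segments with 50% overlap -> LF (0.06-0.6 Hz)
and HF (0.6-2.4 Hz) band powers -> natural-log transform conditioned on
sleep stage.  These are the rat-specific bands: HF tracks vagal
(respiratory-gated) modulation, LF mixed sympathetic/vagal modulation, and
log LF - log HF indexes sympathovagal balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .io import DataError, ValidationError
from .spectral import sliding_spectrum

LF_BAND = (0.06, 0.6)
HF_BAND = (0.6, 2.4)

SEGMENT_COLUMNS = ["t_start_s", "mean_rr_ms", "lf_ms2", "hf_ms2", "stage"]


def detect_r_peaks(ecg: np.ndarray, fs: float = 500.0) -> np.ndarray:
    """R-peak times (s) by band-pass/square/integrate with adaptive threshold.

    5-40 Hz band-pass, squaring, 60-ms moving-window integration, peaks above
    an adaptive threshold with a 60-ms refractory period, each refined to the
    local maximum of the raw trace within +-40 ms.
    """
    x = np.asarray(ecg, dtype=float)
    if len(x) < 10 * fs:
        raise DataError("need at least 10 s of ECG")
    sos = signal.butter(2, [5.0, 40.0], btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    sq = filt ** 2
    win = max(int(round(0.060 * fs)), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")
    height = 0.2 * np.percentile(integ, 99)
    if height <= 0:
        warnings.warn("no QRS energy above threshold; returning no beats")
        return np.empty(0)
    locs, _ = signal.find_peaks(
        integ, height=height, distance=max(int(round(0.060 * fs)), 1)
    )
    if len(locs) == 0:
        warnings.warn("no QRS energy above threshold; returning no beats")
        return np.empty(0)
    # refine on a lightly smoothed trace: sample-level noise would otherwise
    # shift the apex by +-1 sample
    k = np.hanning(max(int(round(0.018 * fs)), 3))
    smooth = np.convolve(x, k / k.sum(), mode="same")
    half = int(round(0.040 * fs))
    refined = np.empty(len(locs), dtype=int)
    for i, c in enumerate(locs):
        lo, hi = max(c - half, 0), min(c + half + 1, len(x))
        refined[i] = lo + int(np.argmax(smooth[lo:hi]))
    refined = np.unique(refined)
    return refined / fs


@dataclass
class RRSeries:
    """Beat times (s), RR intervals (ms), and an artifact mask.

    ``rr[i]`` is the interval ending at ``beat_times[i+1]``; masked intervals
    are excluded from resampling support and bridged by interpolation.
    """

    beat_times: np.ndarray
    rr: np.ndarray
    artifact_mask: np.ndarray  # True = artifact


def rr_tachogram(
    beat_times: np.ndarray,
    physiologic_bounds: Tuple[float, float] = (100.0, 350.0),
) -> RRSeries:
    """RR tachogram with physiologic-bounds and median-deviation masking.

    An interval is masked when it falls outside ``physiologic_bounds`` (ms)
    or deviates more than 30% from the median of the surrounding 9 intervals.
    """
    bt = np.asarray(beat_times, dtype=float)
    if len(bt) < 2:
        raise DataError("need at least 2 beats for a tachogram")
    rr = np.diff(bt) * 1000.0
    mask = (rr < physiologic_bounds[0]) | (rr > physiologic_bounds[1])
    med = (
        pd.Series(rr)
        .rolling(window=9, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.abs(rr - med) / med
    mask |= dev > 0.30
    if mask.all():
        warnings.warn("all RR intervals masked as artifacts")
    return RRSeries(beat_times=bt, rr=rr, artifact_mask=mask)


def resample_rr(
    rr_series: RRSeries, rate: float = 64.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Cubic interpolation of the tachogram onto a uniform grid.

    Each unmasked interval contributes the point (time of its ending beat,
    RR in ms); the grid spans the first to last such beat at ``rate`` Hz.
    Returns (times_s, rr_ms).
    """
    keep = ~rr_series.artifact_mask
    if keep.sum() < 2:
        raise DataError("need at least 2 unmasked intervals to resample")
    t = rr_series.beat_times[1:][keep]
    v = rr_series.rr[keep]
    if t[-1] - t[0] < 16.0:
        raise DataError(
            f"tachogram span {t[-1] - t[0]:.1f} s < 16 s; no full segment"
        )
    grid = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * rate)) + 1) / rate
    return grid, CubicSpline(t, v)(grid)


def hrv_spectra(
    times: np.ndarray,
    values: np.ndarray,
    rate: float = 64.0,
    lf_band: Tuple[float, float] = LF_BAND,
    hf_band: Tuple[float, float] = HF_BAND,
) -> pd.DataFrame:
    """Per-segment LF/HF band powers from the uniform 64 Hz RR series.

    1024-sample (16 s) segments, 512-sample hop, mean removal + Hamming
    taper + periodogram; LF sums bins in [0.06, 0.6) Hz, HF in [0.6, 2.4] Hz
    (1/16 Hz resolution).  Powers are in ms^2.  Returns SEGMENT_COLUMNS with
    ``stage`` unassigned.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < int(16 * rate):
        raise DataError("series shorter than one 16-s segment")
    spec = sliding_spectrum(v, rate, window_s=16.0, hop_s=8.0)
    f = spec.freqs
    lf_mask = (f >= lf_band[0]) & (f < lf_band[1])
    hf_mask = (f >= hf_band[0]) & (f <= hf_band[1])
    n = int(16 * rate)
    hop = int(8 * rate)
    rows = []
    for i, t0 in enumerate(spec.times):
        seg = v[i * hop : i * hop + n]
        rows.append(
            (
                float(times[0] + t0),
                float(seg.mean()),
                float(spec.power[i, lf_mask].sum()),
                float(spec.power[i, hf_mask].sum()),
                "",
            )
        )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def assign_stages(
    segments: pd.DataFrame,
    labels: np.ndarray,
    epoch_len_s: float = 8.0,
    rule: str = "both",
) -> pd.DataFrame:
    """Attach a sleep stage to each 16-s HRV segment.

    ``rule='both'`` (conservative default): a segment gets a stage only when
    every epoch it overlaps carries that same non-ERR label.
    ``rule='majority'``: the most frequent non-ERR label among overlapped
    epochs, ties unassigned.
    """
    if rule not in ("both", "majority"):
        raise ValidationError(f"unknown stage rule {rule!r}")
    labels = np.asarray(labels)
    out = segments.copy()
    stages = []
    for t0 in out["t_start_s"]:
        lo = int(np.floor(t0 / epoch_len_s))
        hi = int(np.ceil((t0 + 16.0) / epoch_len_s))
        cov = labels[max(lo, 0) : hi]
        cov = cov[cov != "ERR"] if len(cov) else cov
        n_overlap = hi - max(lo, 0)
        if len(cov) == 0 or hi > len(labels) or lo < 0:
            stages.append("")
        elif rule == "both":
            stages.append(cov[0] if len(cov) == n_overlap and len(set(cov)) == 1 else "")
        else:
            vals, counts = np.unique(cov, return_counts=True)
            top = counts.max()
            stages.append(vals[counts == top][0] if (counts == top).sum() == 1 else "")
    out["stage"] = stages
    return out


def stage_conditioned_hrv(
    segments: pd.DataFrame,
    labels: Optional[np.ndarray] = None,
    epoch_len_s: float = 8.0,
    rule: str = "both",
    aggregate: str = "log_of_mean",
) -> pd.DataFrame:
    """Overall and per-stage HRV summary in natural-log units.

    For each of overall/AW/QS/PS with at least one assigned segment:
    mean RR (ms), log_lf and log_hf — the natural log of the mean band
    power (``aggregate='log_of_mean'``, default) or the mean of per-segment
    logs (``'mean_of_logs'``) — and log_lfhf = log_lf - log_hf (exact
    identity).  Stages without segments are absent from the result.
    """
    if aggregate not in ("log_of_mean", "mean_of_logs"):
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    seg = segments
    if labels is not None:
        seg = assign_stages(segments, labels, epoch_len_s, rule)
    rows = []
    for name in ("overall", "AW", "QS", "PS"):
        sub = seg if name == "overall" else seg[seg["stage"] == name]
        if len(sub) == 0:
            continue
        lf = sub["lf_ms2"].to_numpy()
        hf = sub["hf_ms2"].to_numpy()
        if aggregate == "log_of_mean":
            log_lf = float(np.log(lf.mean())) if lf.mean() > 0 else np.nan
            log_hf = float(np.log(hf.mean())) if hf.mean() > 0 else np.nan
        else:
            with np.errstate(divide="ignore"):
                log_lf = float(np.mean(np.log(lf[lf > 0]))) if (lf > 0).any() else np.nan
                log_hf = float(np.mean(np.log(hf[hf > 0]))) if (hf > 0).any() else np.nan
        rows.append(
            {
                "stage": name,
                "n_segments": len(sub),
                "mean_rr_ms": float(sub["mean_rr_ms"].mean()),
                "log_lf": log_lf,
                "log_hf": log_hf,
                "log_lfhf": log_lf - log_hf,
            }
        )
    return pd.DataFrame(rows).set_index("stage")


def write_segments_csv(segments: pd.DataFrame, path) -> None:
    segments.to_csv(path, index=False)


def write_stage_hrv_csv(stage_hrv: pd.DataFrame, path) -> None:
    stage_hrv.to_csv(path)
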