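"""Histogram-threshold sleep staging and sleep-architecture metrics.

Stage scoring follows the classical rodent two-feature rule: per 5-h
segment, the histogram of EEG mean power frequency (MPF) separates the
AW/PS complex from QS, and the histogram of log EMG power separates AW from
the QS/PS complex.  Each histogram is split automatically at the
between-class-variance-maximizing point (1-D Otsu), standing in for the
original manual fine-tuning; manual overrides are accepted and recorded.
Epochs are then classified exhaustively:

    MPF > T_MPF, EMG > T_EMG  -> AW
    MPF <= T_MPF, EMG <= T_EMG -> QS
    MPF > T_MPF, EMG <= T_EMG  -> PS   (paradoxical sleep: cortical
                                        activation with muscle atonia)
    MPF <= T_MPF, EMG > T_EMG  -> ERR  (physiologically implausible;
                                        excluded from all downstream rates)

A stage bout is formed from >=6 consecutive identical epochs; any shorter
run is an interruption event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import DataError, ValidationError

AW, QS, PS, ERR = "AW", "QS", "PS", "ERR"
STAGES = (AW, QS, PS)
TRANSITION_KEYS = ("A-Q", "A-P", "Q-A", "Q-P", "P-A", "P-Q")
_PAIR = {(AW, QS): "A-Q", (AW, PS): "A-P", (QS, AW): "Q-A",
         (QS, PS): "Q-P", (PS, AW): "P-A", (PS, QS): "P-Q"}


@dataclass
class Thresholds:
    """Per-segment staging thresholds with bimodality diagnostics.

    ``bimodality_*`` is Sarle's bimodality coefficient (skew^2 + 1) /
    kurtosis, ~0.33 for a Gaussian and ->1 for two well-separated modes;
    histograms scoring below ``BIMODALITY_FLOOR`` are flagged as unimodal.
    ``separability_*`` is Otsu's eta (between-class over total variance).
    """

    t_mpf: float
    t_emg: float
    segment_id: int
    bimodality_mpf: float = np.nan
    bimodality_emg: float = np.nan
    separability_mpf: float = np.nan
    separability_emg: float = np.nan
    flagged: bool = False
    manual_override: Dict[str, float] = field(default_factory=dict)


BIMODALITY_FLOOR = 0.5


def bimodality_coefficient(values) -> float:
    """Sarle's bimodality coefficient (skew^2 + 1) / kurtosis (non-excess)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 4 or np.ptp(x) == 0:
        return 0.0
    z = (x - x.mean()) / x.std()
    skew = np.mean(z ** 3)
    kurt = np.mean(z ** 4)
    return float((skew ** 2 + 1.0) / kurt) if kurt > 0 else 0.0


def otsu_threshold(values: Sequence[float], bins: int = 128) -> Tuple[float, float]:
    """1-D Otsu split of a histogram: threshold maximizing between-class
    variance.  Returns (threshold, eta) where eta = sigma_B^2 / sigma^2.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise DataError("no finite values for thresholding")
    if np.ptp(x) == 0:
        warnings.warn("degenerate histogram: all values identical", stacklevel=2)
        return float(x[0]), 0.0
    counts, edges = np.histogram(x, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = counts / counts.sum()
    mu = np.cumsum(w * centers)
    omega = np.cumsum(w)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    k = int(np.argmax(sigma_b[:-1]))
    eta = float(sigma_b[k] / np.var(x)) if np.var(x) > 0 else 0.0
    return float(edges[k + 1]), eta


def estimate_thresholds(
    features: pd.DataFrame,
    segment_len_s: float = 5 * 3600.0,
    min_segment_s: float = 1800.0,
    overrides: Optional[Dict[int, Dict[str, float]]] = None,
) -> Tuple[List[Thresholds], np.ndarray]:
    """Otsu thresholds on MPF and log-EMG-power histograms per 5-h segment.

    The final partial segment keeps its own thresholds when it is at least
    30 min long, otherwise it reuses the previous segment's.  Returns the
    per-segment thresholds and the per-epoch segment assignment.

    ``overrides`` maps segment_id -> {"t_mpf": ..., "t_emg": ...}; override
    values replace the automatic split and are recorded for provenance.
    """
    if len(features) == 0:
        raise DataError("no epochs to threshold")
    t = features["t_start_s"].to_numpy(dtype=float)
    epoch_len = float(np.median(np.diff(t))) if len(t) > 1 else 8.0
    # each feature window spans two epochs, so n features cover n+1 epochs
    total_s = (len(features) + 1) * epoch_len
    if total_s < min_segment_s:
        raise DataError(
            f"recording too short for thresholding "
            f"({total_s:.0f} s < {min_segment_s:.0f} s)"
        )
    seg_ids = np.minimum(
        (t // segment_len_s).astype(int),
        max(int((total_s - 1) // segment_len_s), 0),
    )
    last = seg_ids.max()
    if last > 0:
        last_len = (seg_ids == last).sum() * epoch_len
        if last_len < min_segment_s:
            seg_ids[seg_ids == last] = last - 1
            last -= 1

    out: List[Thresholds] = []
    overrides = overrides or {}
    for sid in range(last + 1):
        m = seg_ids == sid
        mpf = features.loc[m, "mpf_hz"].to_numpy()
        emg = features.loc[m, "emg_power"].to_numpy()
        t_mpf, eta_mpf = otsu_threshold(mpf)
        with np.errstate(divide="ignore"):
            log_emg = np.log10(np.maximum(emg, np.finfo(float).tiny))
        t_log_emg, eta_emg = otsu_threshold(log_emg)
        bc_mpf = bimodality_coefficient(mpf)
        bc_emg = bimodality_coefficient(log_emg)
        th = Thresholds(
            t_mpf=t_mpf,
            t_emg=float(10.0 ** t_log_emg),
            segment_id=sid,
            bimodality_mpf=bc_mpf,
            bimodality_emg=bc_emg,
            separability_mpf=eta_mpf,
            separability_emg=eta_emg,
        )
        if bc_mpf < BIMODALITY_FLOOR or bc_emg < BIMODALITY_FLOOR:
            th.flagged = True
            warnings.warn(
                f"segment {sid}: histogram looks unimodal "
                f"(bimodality MPF={bc_mpf:.2f}, EMG={bc_emg:.2f}); "
                "threshold may be unreliable",
                stacklevel=2,
            )
        ov = overrides.get(sid)
        if ov:
            th.manual_override = dict(ov)
            th.t_mpf = float(ov.get("t_mpf", th.t_mpf))
            th.t_emg = float(ov.get("t_emg", th.t_emg))
        out.append(th)
    return out, seg_ids


def classify_epochs(
    features: pd.DataFrame,
    thresholds: Sequence[Thresholds],
    segment_ids: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Four-way threshold rule; 'above' is strict, 'below' non-strict.

    Epochs with missing (NaN) features are marked ERR.
    """
    if segment_ids is None:
        segment_ids = np.zeros(len(features), dtype=int)
    by_id = {th.segment_id: th for th in thresholds}
    mpf = features["mpf_hz"].to_numpy(dtype=float)
    emg = features["emg_power"].to_numpy(dtype=float)
    labels = np.empty(len(features), dtype="<U3")
    for i in range(len(features)):
        th = by_id.get(int(segment_ids[i]))
        if th is None:
            raise ValidationError(f"no thresholds for segment {segment_ids[i]}")
        if not (np.isfinite(mpf[i]) and np.isfinite(emg[i])):
            labels[i] = ERR
            continue
        hi_mpf = mpf[i] > th.t_mpf
        hi_emg = emg[i] > th.t_emg
        if hi_mpf and hi_emg:
            labels[i] = AW
        elif not hi_mpf and not hi_emg:
            labels[i] = QS
        elif hi_mpf:
            labels[i] = PS
        else:
            labels[i] = ERR
    return labels


@dataclass
class Bout:
    stage: str
    start: int  # epoch index
    length: int  # epochs


@dataclass
class Interruption:
    stage: str
    start: int
    length: int


def form_stages(
    labels: np.ndarray, min_run: int = 6
) -> Tuple[List[Bout], List[Interruption]]:
    """Split the label series into bouts (runs >= min_run) and interruption
    events (runs < min_run).  ERR epochs break runs and belong to neither."""
    bouts: List[Bout] = []
    inter: List[Interruption] = []
    n = len(labels)
    i = 0
    while i < n:
        if labels[i] == ERR:
            i += 1
            continue
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        run = j - i
        if run >= min_run:
            bouts.append(Bout(str(labels[i]), i, run))
        else:
            inter.append(Interruption(str(labels[i]), i, run))
        i = j
    return bouts, inter


@dataclass
class SleepArchitecture:
    """Sleep architecture over the valid (non-ERR) part of a recording."""

    time_pct: Dict[str, float]
    mean_bout_dur_s: Dict[str, float]
    interruption_rate: float  # events per valid minute (all stages)
    qs_interruption_rate: float  # QS-flanked events per QS minute
    transitions: Dict[str, int]
    qs_band_profile_pct: Dict[str, float]
    n_valid_epochs: int
    n_err_epochs: int


def architecture_metrics(
    labels: np.ndarray,
    bouts: Sequence[Bout],
    interruptions: Sequence[Interruption],
    features: Optional[pd.DataFrame] = None,
    epoch_len_s: float = 8.0,
) -> SleepArchitecture:
    """Aggregate labels/bouts/interruptions into architecture metrics.

    ``interruption_rate`` normalizes all interruption events by total valid
    minutes; ``qs_interruption_rate`` is the stricter variant counting only
    events flanked by QS on both sides, per minute of QS.
    Transitions are counted between consecutive formed bouts.
    ``qs_band_profile_pct`` holds mean EEG band fractions over QS epochs in
    normalized units (percent), when features are supplied.
    """
    labels = np.asarray(labels)
    valid = labels != ERR
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise DataError("no valid (non-ERR) epochs")
    valid_min = n_valid * epoch_len_s / 60.0

    time_pct = {
        s: 100.0 * float((labels == s).sum()) / n_valid for s in STAGES
    }
    mean_bout = {}
    for s in STAGES:
        lens = [b.length for b in bouts if b.stage == s]
        mean_bout[s] = float(np.mean(lens)) * epoch_len_s if lens else np.nan

    rate = len(interruptions) / valid_min

    # QS-scoped variant: events whose neighboring non-ERR runs are both QS
    bout_keys = {(b.start, b.length, b.stage) for b in bouts}
    runs = sorted(
        list(bout_keys) + [(e.start, e.length, e.stage) for e in interruptions]
    )
    qs_events = 0
    for idx, (_s, _l, stage) in enumerate(runs):
        if (_s, _l, stage) in bout_keys:
            continue
        prev_qs = idx > 0 and runs[idx - 1][2] == QS
        next_qs = idx + 1 < len(runs) and runs[idx + 1][2] == QS
        if prev_qs and next_qs:
            qs_events += 1
    qs_min = (labels == QS).sum() * epoch_len_s / 60.0
    qs_rate = qs_events / qs_min if qs_min > 0 else np.nan

    transitions = {k: 0 for k in TRANSITION_KEYS}
    bout_seq = [b.stage for b in sorted(bouts, key=lambda b: b.start)]
    for a, b in zip(bout_seq[:-1], bout_seq[1:]):
        key = _PAIR.get((a, b))
        if key is not None:
            transitions[key] += 1

    profile = {}
    if features is not None:
        qs_mask = labels == QS
        if qs_mask.any():
            sub = features.loc[qs_mask[: len(features)]]
            for band in ("delta", "theta", "alpha", "beta"):
                profile[band] = 100.0 * float(sub[f"{band}_fr"].mean())

    return SleepArchitecture(
        time_pct=time_pct,
        mean_bout_dur_s=mean_bout,
        interruption_rate=float(rate),
        qs_interruption_rate=float(qs_rate),
        transitions=transitions,
        qs_band_profile_pct=profile,
        n_valid_epochs=n_valid,
        n_err_epochs=int((~valid).sum()),
    )


def staging_recovery_report(
    predicted: np.ndarray, truth: np.ndarray
) -> Tuple[pd.DataFrame, float]:
    """Confusion matrix (truth x predicted) and accuracy over non-ERR
    predictions."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise DataError(
            f"length mismatch: {len(predicted)} predicted vs {len(truth)} truth"
        )
    cm = pd.DataFrame(
        0, index=list(STAGES), columns=list(STAGES) + [ERR], dtype=int
    )
    for t, p in zip(truth, predicted):
        cm.loc[t, p] += 1
    scored = predicted != ERR
    acc = (
        float((predicted[scored] == truth[scored]).mean()) if scored.any() else np.nan
    )
    return cm, acc


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_hypnogram_csv(labels: np.ndarray, path, epoch_len_s: float = 8.0) -> None:
    pd.DataFrame(
        {
            "epoch_index": np.arange(len(labels)),
            "t_start_s": epoch_len_s * np.arange(len(labels)),
            "label": labels,
        }
    ).to_csv(path, index=False)


def write_bouts_csv(bouts: Sequence[Bout], path, epoch_len_s: float = 8.0) -> None:
    pd.DataFrame(
        [
            {
                "stage": b.stage,
                "start_s": b.start * epoch_len_s,
                "end_s": (b.start + b.length) * epoch_len_s,
                "n_epochs": b.length,
            }
            for b in bouts
        ],
        columns=["stage", "start_s", "end_s", "n_epochs"],
    ).to_csv(path, index=False)


def architecture_row(arch: SleepArchitecture) -> Dict[str, float]:
    """Flatten a SleepArchitecture into the standard report row."""
    row = {
        "AW_pct": arch.time_pct[AW],
        "QS_pct": arch.time_pct[QS],
        "PS_pct": arch.time_pct[PS],
        "interruption_per_min": arch.interruption_rate,
        "qs_interruption_per_min": arch.qs_interruption_rate,
    }
    for band in ("delta", "theta", "alpha", "beta"):
        row[f"QS_{band}_pct"] = arch.qs_band_profile_pct.get(band, np.nan)
    return row


def write_architecture_csv(arch: SleepArchitecture, path) -> None:
    pd.DataFrame([architecture_row(arch)]).to_csv(path, index=False)
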