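"""Recording container, run configuration, and signal I/O (EDF + lossless NPZ).

The interchange format is EDF (European Data Format), the de-facto standard
for polysomnography.  EDF stores each channel at its own sampling rate but
quantizes samples to 16 bits, so a lossless NPZ container is provided for
internal round trips.  The reader/writer here implements the plain EDF layout
directly: a 256-byte fixed-width ASCII header, 256 ASCII bytes per signal,
then little-endian int16 data records (one second per record).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator


class ValidationError(ValueError):
    """Invalid configuration or parameter (CLI exit code 2)."""


class DataError(RuntimeError):
    """Malformed, missing, or inconsistent input data (CLI exit code 3)."""


# Channel roles and their acquisition constants: sampling rate (Hz) and
# analog passband (Hz) of the telemetry front-end.
CHANNEL_RATES: Dict[str, float] = {"eeg": 125.0, "emg": 250.0, "ecg": 500.0}
CHANNEL_PASSBANDS: Dict[str, Tuple[float, float]] = {
    "eeg": (0.16, 48.0),
    "emg": (34.0, 103.0),
    "ecg": (0.72, 103.0),
}

#: Regex patterns used to map EDF channel labels onto roles.
DEFAULT_LABEL_PATTERNS: Dict[str, str] = {
    "eeg": r"(?i)\beeg\b|^eeg",
    "emg": r"(?i)\bemg\b|^emg",
    "ecg": r"(?i)\becg\b|^ecg|ekg",
}


@dataclass
class Recording:
    """Synchronized EEG/EMG/ECG traces with per-channel sampling rates.

    Attributes
    ----------
    channels : dict
        role -> 1-D float array of samples.
    fs : dict
        role -> sampling rate in Hz.
    start_time : datetime
    provenance : dict
        Free-form; carries ``source``, ``config_hash`` and, for synthetic
        recordings, the generator ``seed``.
    """

    channels: Dict[str, np.ndarray]
    fs: Dict[str, float] = field(default_factory=lambda: dict(CHANNEL_RATES))
    start_time: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2000, 1, 1, 0, 0, 0)
    )
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        role = min(self.fs, key=self.fs.get)
        return len(self.channels[role]) / self.fs[role]

    def validate(self, expected_rates: Optional[Dict[str, float]] = None) -> None:
        """Check channel roles, rates, and span consistency.

        All channels must span the same duration within one sample period of
        the slowest channel.
        """
        rates = CHANNEL_RATES if expected_rates is None else expected_rates
        for role in rates:
            if role not in self.channels:
                raise DataError(f"missing channel role: {role!r}")
            if not np.isclose(self.fs[role], rates[role]):
                raise DataError(
                    f"channel {role!r} has rate {self.fs[role]} Hz, "
                    f"expected {rates[role]} Hz"
                )
        slowest = min(self.fs.values())
        tol = 1.0 / slowest
        durs = {r: len(x) / self.fs[r] for r, x in self.channels.items()}
        if max(durs.values()) - min(durs.values()) > tol + 1e-9:
            raise DataError(f"channel durations differ beyond tolerance: {durs}")


class RunConfig(BaseModel):
    """Analysis constants for the full pipeline.

    The defaults are the constants of the acquisition/analysis protocol:
    8-s epochs scored from 16-s Hamming windows with 50% overlap, stages
    formed from >=6 identical epochs, thresholds per 5-h segment, RR series
    resampled at 64 Hz and analyzed in 1024-point (16-s) segments with LF
    0.06-0.6 Hz and HF 0.6-2.4 Hz.
    """

    epoch_len_s: float = 8.0
    window_s: float = 16.0
    min_run: int = 6
    segment_len_s: float = 5 * 3600.0
    min_segment_s: float = 1800.0
    mpf_band: Tuple[float, float] = (1.0, 32.0)
    eeg_bands: Dict[str, Tuple[float, float]] = Field(
        default_factory=lambda: {
            "delta": (1.0, 4.0),
            "theta": (4.0, 8.0),
            "alpha": (8.0, 13.0),
            "beta": (13.0, 32.0),
        }
    )
    emg_band: Tuple[float, float] = (34.0, 103.0)
    rr_resample_hz: float = 64.0
    hrv_segment_samples: int = 1024
    lf_band: Tuple[float, float] = (0.06, 0.6)
    hf_band: Tuple[float, float] = (0.6, 2.4)
    rr_physiologic_bounds: Tuple[float, float] = (100.0, 350.0)
    interruption_scope: str = "total"  # "total" or "qs"
    stage_rule: str = "both"  # HRV segment-to-stage rule: "both" or "majority"
    hrv_aggregate: str = "log_of_mean"  # or "mean_of_logs"
    stats_policy: str = "auto"
    normality_alpha: float = 0.05

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.epoch_len_s <= 0 or self.window_s <= 0:
            raise ValueError("epoch/window lengths must be positive")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.interruption_scope not in ("total", "qs"):
            raise ValueError("interruption_scope must be 'total' or 'qs'")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# EDF writer / reader
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _fmt_float(v: float, width: int = 8) -> str:
    for fmt in (f"{v:.10g}", f"{v:.6g}", f"{v:.4g}", f"{v:.2g}"):
        if len(fmt) <= width:
            return fmt
    return fmt[:width]


def write_edf(recording: Recording, path, labels: Optional[Dict[str, str]] = None) -> None:
    """Write a Recording as plain EDF, one data record per second.

    Each channel keeps its true sampling rate (samples-per-record = fs).
    Samples are scaled to the int16 range of each channel's observed
    physical min/max; the duration is truncated to whole seconds.
    """
    labels = labels or {"eeg": "EEG parietal", "emg": "EMG nuchal", "ecg": "ECG"}
    roles = sorted(recording.channels, key=lambda r: recording.fs[r])
    n_sec = int(min(len(recording.channels[r]) / recording.fs[r] for r in roles))
    if n_sec < 1:
        raise DataError("recording shorter than one EDF data record (1 s)")
    ns = len(roles)

    digital = {}
    phys = {}
    for r in roles:
        fs = recording.fs[r]
        if abs(fs - round(fs)) > 1e-9:
            raise DataError(f"EDF with 1-s records needs integer rates, got {fs}")
        x = np.asarray(recording.channels[r], dtype=float)[: n_sec * int(fs)]
        pmin, pmax = float(np.min(x)), float(np.max(x))
        if pmax <= pmin:
            pmax = pmin + 1.0
        # round-trip the header ASCII so scaling matches what a reader parses
        pmin = float(_fmt_float(pmin))
        pmax = float(_fmt_float(pmax))
        gain = (pmax - pmin) / 65535.0
        dig = np.clip(np.round((x - pmin) / gain) - 32768, -32768, 32767)
        digital[r] = dig.astype("<i2")
        phys[r] = (pmin, pmax)

    start = recording.start_time
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii(start.strftime("%d.%m.%y"), 8),
            _ascii(start.strftime("%H.%M.%S"), 8),
            _ascii(256 * (ns + 1), 8),
            _ascii("", 44),
            _ascii(n_sec, 8),
            _ascii("1", 8),
            _ascii(ns, 4),
        ]
    )
    fields = [
        b"".join(_ascii(labels.get(r, r.upper()), 16) for r in roles),
        b"".join(_ascii("", 80) for _ in roles),
        b"".join(_ascii("uV", 8) for _ in roles),
        b"".join(_ascii(_fmt_float(phys[r][0]), 8) for r in roles),
        b"".join(_ascii(_fmt_float(phys[r][1]), 8) for r in roles),
        b"".join(_ascii(-32768, 8) for _ in roles),
        b"".join(_ascii(32767, 8) for _ in roles),
        b"".join(
            _ascii("HP:{:g}Hz LP:{:g}Hz".format(*CHANNEL_PASSBANDS.get(r, (0, 0))), 80)
            for r in roles
        ),
        b"".join(_ascii(int(recording.fs[r]), 8) for r in roles),
        b"".join(_ascii("", 32) for _ in roles),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        spr = {r: int(recording.fs[r]) for r in roles}
        for sec in range(n_sec):
            for r in roles:
                fh.write(digital[r][sec * spr[r] : (sec + 1) * spr[r]].tobytes())


def read_edf(path) -> Tuple[Dict[str, Tuple[float, np.ndarray]], _dt.datetime]:
    """Parse an EDF file; returns {label: (fs, samples)} and the start time."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise DataError(f"{path}: truncated EDF header")
        try:
            n_rec = int(head[236:244].decode("ascii").strip())
            rec_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
            date_s = head[168:176].decode("ascii").strip()
            time_s = head[176:184].decode("ascii").strip()
        except (UnicodeDecodeError, ValueError) as exc:
            raise DataError(f"{path}: not a valid EDF header") from exc
        sig = fh.read(256 * ns)

        def col(offset, width):
            base = offset * ns
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels_raw = col(0, 16)
        pmin = [float(v) for v in col(16 + 80 + 8, 8)]
        pmax = [float(v) for v in col(16 + 80 + 8 + 8, 8)]
        dmin = [int(v) for v in col(16 + 80 + 8 + 16, 8)]
        dmax = [int(v) for v in col(16 + 80 + 8 + 24, 8)]
        spr = [int(v) for v in col(16 + 80 + 8 + 32 + 80, 8)]

        data = {lab: [] for lab in labels_raw}
        for _ in range(n_rec):
            for i, lab in enumerate(labels_raw):
                raw = fh.read(2 * spr[i])
                if len(raw) < 2 * spr[i]:
                    raise DataError(f"{path}: truncated EDF data record")
                data[lab].append(np.frombuffer(raw, dtype="<i2"))

    out = {}
    for i, lab in enumerate(labels_raw):
        dig = np.concatenate(data[lab]).astype(float)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        out[lab] = (spr[i] / rec_dur, pmin[i] + (dig - dmin[i]) * gain)
    try:
        start = _dt.datetime.strptime(date_s + " " + time_s, "%d.%m.%y %H.%M.%S")
    except ValueError:
        start = _dt.datetime(2000, 1, 1)
    return out, start


# ---------------------------------------------------------------------------
# Lossless internal container
# ---------------------------------------------------------------------------

def write_npz(recording: Recording, path) -> None:
    meta = {
        "fs": recording.fs,
        "start_time": recording.start_time.isoformat(),
        "provenance": recording.provenance,
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta, default=str).encode(), dtype=np.uint8),
        **{f"ch_{r}": x for r, x in recording.channels.items()},
    )


def read_npz(path) -> Recording:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        channels = {
            k[3:]: z[k].copy() for k in z.files if k.startswith("ch_")
        }
    return Recording(
        channels=channels,
        fs={k: float(v) for k, v in meta["fs"].items()},
        start_time=_dt.datetime.fromisoformat(meta["start_time"]),
        provenance=meta.get("provenance", {}),
    )


def read_recording(
    path,
    format: str = "auto",
    label_patterns: Optional[Dict[str, str]] = None,
    expected_rates: Optional[Dict[str, float]] = None,
) -> Recording:
    """Load a Recording from EDF or the internal NPZ container.

    EDF channel labels are mapped onto the eeg/emg/ecg roles with
    configurable regex patterns; rates are validated against the expected
    per-role rates (125/250/500 Hz by default).
    """
    fmt = format
    if fmt == "auto":
        fmt = "npz" if str(path).endswith(".npz") else "edf"
    if fmt == "npz":
        rec = read_npz(path)
        rec.validate(expected_rates)
        return rec
    if fmt != "edf":
        raise ValidationError(f"unknown recording format: {format!r}")

    patterns = label_patterns or DEFAULT_LABEL_PATTERNS
    raw, start = read_edf(path)
    channels, fs = {}, {}
    for role, pat in patterns.items():
        matches = [lab for lab in raw if re.search(pat, lab)]
        if not matches:
            raise DataError(
                f"no channel matching role {role!r} (pattern {pat!r}) "
                f"among labels {sorted(raw)}"
            )
        rate, samples = raw[matches[0]]
        channels[role], fs[role] = samples, rate
    rec = Recording(
        channels=channels, fs=fs, start_time=start,
        provenance={"source": str(path), "format": "edf"},
    )
    rec.validate(expected_rates)
    return rec
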