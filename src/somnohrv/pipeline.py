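"""End-to-end composition: recording -> features -> hypnogram -> HRV tables.

``run_pipeline`` wires the modules together under a single RunConfig,
optionally writing every intermediate table as CSV (each carrying the
config hash for provenance), and logs thresholds, overrides, artifact-mask
counts and dropped segments.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import hrv as _hrv
from . import spectral, staging
from .io import DataError, Recording, RunConfig

log = logging.getLogger("somnohrv")


def run_pipeline(
    recording: Recording,
    run_config: Optional[RunConfig] = None,
    outdir: Optional[str] = None,
    threshold_overrides: Optional[Dict[int, Dict[str, float]]] = None,
) -> Dict[str, object]:
    """Full analysis of one recording.

    Returns a bundle with keys: features, thresholds, segment_ids, labels,
    bouts, interruptions, architecture, rr, segments, stage_hrv,
    config_hash.  With ``outdir`` set, writes features.csv, hypnogram.csv,
    bouts.csv, architecture.csv, hrv_segments.csv, stage_hrv.csv.
    """
    cfg = run_config or RunConfig()
    chash = cfg.config_hash()
    recording.validate()

    eeg_spec = spectral.sliding_spectrum(
        recording.channels["eeg"], recording.fs["eeg"], cfg.window_s, cfg.epoch_len_s
    )
    emg_spec = spectral.sliding_spectrum(
        recording.channels["emg"], recording.fs["emg"], cfg.window_s, cfg.epoch_len_s
    )
    features = spectral.epoch_features(
        eeg_spec, emg_spec, mpf_band=cfg.mpf_band, emg_band=cfg.emg_band
    )
    log.info("features: %d epochs", len(features))

    thresholds, segment_ids = staging.estimate_thresholds(
        features,
        segment_len_s=cfg.segment_len_s,
        min_segment_s=cfg.min_segment_s,
        overrides=threshold_overrides,
    )
    for th in thresholds:
        log.info(
            "segment %d: T_MPF=%.3f Hz (eta=%.2f) T_EMG=%.4g (eta=%.2f)%s%s",
            th.segment_id, th.t_mpf, th.separability_mpf, th.t_emg,
            th.separability_emg,
            " [flagged]" if th.flagged else "",
            f" [override {th.manual_override}]" if th.manual_override else "",
        )
    labels = staging.classify_epochs(features, thresholds, segment_ids)
    bouts, interruptions = staging.form_stages(labels, min_run=cfg.min_run)
    architecture = staging.architecture_metrics(
        labels, bouts, interruptions, features, epoch_len_s=cfg.epoch_len_s
    )
    log.info(
        "hypnogram: %d bouts, %d interruptions, %d ERR epochs",
        len(bouts), len(interruptions), architecture.n_err_epochs,
    )

    beat_times = _hrv.detect_r_peaks(recording.channels["ecg"], recording.fs["ecg"])
    if len(beat_times) < 2:
        raise DataError("no beats detected; cannot run HRV analysis")
    rr = _hrv.rr_tachogram(beat_times, cfg.rr_physiologic_bounds)
    log.info(
        "tachogram: %d intervals, %d masked", len(rr.rr), int(rr.artifact_mask.sum())
    )
    times, uniform = _hrv.resample_rr(rr, cfg.rr_resample_hz)
    segments = _hrv.hrv_spectra(
        times, uniform, cfg.rr_resample_hz, cfg.lf_band, cfg.hf_band
    )
    segments = _hrv.assign_stages(
        segments, labels, epoch_len_s=cfg.epoch_len_s, rule=cfg.stage_rule
    )
    stage_hrv = _hrv.stage_conditioned_hrv(segments, aggregate=cfg.hrv_aggregate)

    bundle: Dict[str, object] = {
        "features": features,
        "thresholds": thresholds,
        "segment_ids": segment_ids,
        "labels": labels,
        "bouts": bouts,
        "interruptions": interruptions,
        "architecture": architecture,
        "rr": rr,
        "segments": segments,
        "stage_hrv": stage_hrv,
        "config_hash": chash,
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

        def _stamp(df: pd.DataFrame) -> pd.DataFrame:
            df = df.copy()
            df["config_hash"] = chash
            return df

        _stamp(features).to_csv(out / "features.csv", index=False)
        hyp = pd.DataFrame(
            {
                "epoch_index": range(len(labels)),
                "t_start_s": [cfg.epoch_len_s * i for i in range(len(labels))],
                "label": labels,
            }
        )
        _stamp(hyp).to_csv(out / "hypnogram.csv", index=False)
        staging.write_bouts_csv(bouts, out / "bouts.csv", cfg.epoch_len_s)
        _stamp(pd.DataFrame([staging.architecture_row(architecture)])).to_csv(
            out / "architecture.csv", index=False
        )
        _stamp(segments).to_csv(out / "hrv_segments.csv", index=False)
        _stamp(stage_hrv.reset_index()).to_csv(out / "stage_hrv.csv", index=False)
        log.info("tables written to %s (config %s)", out, chash)
    return bundle


def metrics_from_bundle(bundle: Dict[str, object]) -> Dict[str, float]:
    """Flatten one animal's pipeline result into named scalar metrics.

    Produces the sleep-architecture rows (stage %, interruption rates, QS
    band profile) and the HRV rows (per stage and overall: mean RR, log LF,
    log HF, log LF/HF).
    """
    arch = bundle["architecture"]
    out: Dict[str, float] = dict(staging.architecture_row(arch))
    stage_hrv: pd.DataFrame = bundle["stage_hrv"]  # type: ignore[assignment]
    for stage, row in stage_hrv.iterrows():
        out[f"rr_ms_{stage}"] = row["mean_rr_ms"]
        out[f"log_lf_{stage}"] = row["log_lf"]
        out[f"log_hf_{stage}"] = row["log_hf"]
        out[f"log_lfhf_{stage}"] = row["log_lfhf"]
    return out
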