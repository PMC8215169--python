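"""Offline session evaluation under the three band versions.

Learning metrics are recomputed from stored raw segments in three
versions: "actual_online" (the band the subject actually saw — broadband
for sessions 1-2, the subject-specific band after), "broadband" (8-30 Hz
throughout) and "subject_specific" (the 4-Hz band throughout).  Artifact
gating replays the Riemannian Potato on the 1-30 Hz path exactly as
online; only clean segments enter the metrics.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import SessionConfig, advanced_protocol_band, bandpass
from .geometry import EEGSegment, InvalidInputError, estimate_covariance
from .metrics import (
    class_distinctiveness,
    crossval_accuracy,
    discriminancy_map,
    laplacian_derivation,
    learning_trend,
    psd_features,
)
from .potato import classify_segment, initialize_potato, update_potato
from .synth import Session

__all__ = ["gate_session", "run_metrics", "evaluate_session", "BAND_VERSIONS"]

BAND_VERSIONS = ("actual_online", "broadband", "subject_specific")


def gate_session(session: Session, cfg: SessionConfig) -> Dict[int, List[EEGSegment]]:
    """Replay the Potato gate; return the clean segments per run.

    Covariances on the fixed 1-30 Hz path, sequential classify/update with
    state carried across runs, exactly as the online engine does.
    """
    covs = [
        estimate_covariance(bandpass(s, cfg.potato_band, mode="offline"),
                            shrinkage=cfg.shrinkage)
        for s in session.baseline
    ]
    state = initialize_potato(covs, z=cfg.potato_z, w=cfg.potato_w,
                              alpha_ref=cfg.potato_alpha_ref)
    clean: Dict[int, List[EEGSegment]] = {}
    for run in session.runs:
        kept: List[EEGSegment] = []
        for trial in run.trials:
            for seg in trial.segments:
                P = estimate_covariance(
                    bandpass(seg, cfg.potato_band, mode="offline"),
                    shrinkage=cfg.shrinkage,
                )
                is_art, d = classify_segment(state, P)
                if not is_art:
                    state = update_potato(state, P, distance=d)
                    kept.append(seg)
        clean[run.run_id] = kept
    return clean


def _resolve_band(
    version: str,
    session_index: int,
    subject_band: Optional[Tuple[float, float]],
) -> Tuple[float, float]:
    if version == "broadband":
        return (8.0, 30.0)
    if version == "subject_specific":
        if subject_band is None:
            raise InvalidInputError(
                "subject_specific evaluation requires a selected band"
            )
        return tuple(subject_band)
    if version == "actual_online":
        return advanced_protocol_band(SessionConfig(), session_index, subject_band)
    raise InvalidInputError(f"unknown band version {version!r}")


def run_metrics(
    segs: Sequence[EEGSegment],
    band: Tuple[float, float],
    channels: Sequence[str],
    fs: float = 250.0,
    shrinkage: float = 0.01,
    cv_seed: int = 0,
) -> Dict[str, float]:
    """ClassDis, average Fisher score and fivefold MDM CA for one run.

    Segments are zero-phase filtered in ``band`` for the covariance
    metrics; FS features are Laplacian-derived 2-Hz band powers per
    segment within the band (edges widened to the 2-Hz grid).
    """
    labels = [s.label for s in segs]
    if len(set(labels)) < 2:
        raise InvalidInputError("run does not contain both classes")
    covs = [
        estimate_covariance(bandpass(s, band, mode="offline"),
                            shrinkage=shrinkage)
        for s in segs
    ]
    covsA = [P for P, l in zip(covs, labels) if l == "left"]
    covsB = [P for P, l in zip(covs, labels) if l == "right"]
    classdis = class_distinctiveness(covsA, covsB)
    ca = crossval_accuracy(covs, labels, k=5, split="sample", seed=cv_seed)
    lo = 2.0 * np.floor(band[0] / 2.0)
    hi = 2.0 * np.ceil(band[1] / 2.0)
    feats = []
    for s in segs:
        lap = laplacian_derivation(s.samples, channels)
        p, _ = psd_features(lap, fs=fs, band=(lo, hi))
        feats.append(p.mean(axis=0))
    _, _, fs_avg = discriminancy_map(np.stack(feats), labels, channels)
    return {"ClassDis": classdis, "FS_avg": fs_avg, "CA": ca}


def evaluate_session(
    session: Session,
    cfg: Optional[SessionConfig] = None,
    band_version: str = "broadband",
    subject_band: Optional[Tuple[float, float]] = None,
    session_index: int = 1,
    cv_seed: int = 0,
) -> pd.DataFrame:
    """Per-run metric table: ClassDis, FS average and MDM CA for one session.

    Returns a tidy frame with columns (run, session, metric, band_version,
    value).  Only Potato-clean segments enter the metrics.
    """
    if cfg is None:
        cfg = SessionConfig()
    band = _resolve_band(band_version, session_index, subject_band)
    clean = gate_session(session, cfg)
    channels = list(cfg.feedback_channels)
    rows = []
    for run_id in sorted(clean):
        segs = clean[run_id]
        if len({s.label for s in segs}) < 2:
            raise InvalidInputError(f"run {run_id} lost a class after gating")
        vals = run_metrics(segs, band, channels, fs=cfg.fs,
                           shrinkage=cfg.shrinkage, cv_seed=cv_seed)
        for metric, value in vals.items():
            rows.append(
                {"run": run_id, "session": session_index, "metric": metric,
                 "band_version": band_version, "value": value}
            )
    return pd.DataFrame(rows)


def metric_trends(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson learning trend (r, p) per metric across the table's runs."""
    out = []
    for (metric, version), grp in table.groupby(["metric", "band_version"]):
        vals = grp.sort_values("run")["value"].to_numpy()
        r, p = learning_trend(vals)
        out.append({"metric": metric, "band_version": version,
                    "r": r, "p": p, "n": len(vals)})
    return pd.DataFrame(out)
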