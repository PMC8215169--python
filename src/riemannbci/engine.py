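"""Online feedback protocol loop.

Per 1-s motor-imagery segment the engine runs two parallel filter paths:
a fixed 1-30 Hz path feeding the Riemannian Potato artifact gate, and the
feedback band (8-30 Hz broadband in early sessions, a subject-specific
4-Hz band later) feeding the display pipeline.  Clean segments append one
row to the run's pairwise-distance matrix, update their class's running
Fréchet mean, and trigger a diffusion-map re-embedding with the two class
means appended as pseudo-points and axis signs anchored to one of them.
Artifacts are logged and discarded.  Points, frames and class means reset
at run boundaries; the Potato state persists across runs within a session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import signal

from .diffusion import DistanceMatrix, EmbeddingFrame, anchor_signs, embed
from .geometry import (
    ClassState,
    EEGSegment,
    InvalidInputError,
    estimate_covariance,
    incremental_mean_update,
    mean_absolute_deviation,
    riemannian_distance,
)
from .potato import PotatoState, classify_segment, initialize_potato, update_potato
from .synth import Session

__all__ = [
    "SessionConfig",
    "FeedbackUpdate",
    "RunResult",
    "SessionResult",
    "OnlineBandpass",
    "bandpass",
    "FeedbackEngine",
    "run_session",
    "advanced_protocol_band",
    "MEAN_POINT_IDS",
]

MEAN_POINT_IDS = ("mean:left", "mean:right")
ANCHOR_ID = "mean:left"
BROADBAND = (8.0, 30.0)


@dataclass
class SessionConfig:
    """Protocol constants of one training session.

    Defaults mirror the training protocol: 250 Hz sampling, 1-s
    zero-overlap windows, ten feedback channels, 40-trial runs (2-s
    fixation + 4-s MI + 2-s rest), five runs per session, a 10-s resting
    baseline, kernel scale epsilon = 20, Potato z = 2.5, w = 0.01,
    alpha_ref = 100.
    """

    fs: float = 250.0
    window: float = 1.0
    feedback_channels: Tuple[str, ...] = (
        "FC3", "FC4", "C5", "C3", "C1", "C2", "C4", "C6", "CP3", "CP4",
    )
    trials_per_run: int = 40
    runs_per_session: int = 5
    mi_duration: float = 4.0
    fixation: float = 2.0
    rest: float = 2.0
    baseline: float = 10.0
    feedback_band: Tuple[float, float] = BROADBAND
    potato_band: Tuple[float, float] = (1.0, 30.0)
    epsilon: float = 20.0
    potato_z: float = 2.5
    potato_w: float = 0.01
    potato_alpha_ref: float = 100.0
    shrinkage: float = 0.01
    filter_order: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.fs / 2.0
        for lo, hi in (self.feedback_band, self.potato_band):
            if not 0.0 < lo < hi < nyq:
                raise InvalidInputError("band limits must lie within (0, fs/2)")
        if not self.feedback_channels:
            raise InvalidInputError("channel list must be non-empty")
        n_seg = self.mi_duration / self.window
        if abs(n_seg - round(n_seg)) > 1e-9:
            raise InvalidInputError("mi_duration must be a multiple of window")

    @property
    def segments_per_trial(self) -> int:
        return int(round(self.mi_duration / self.window))


@dataclass
class FeedbackUpdate:
    """Outcome of one processed segment: gate decision, optional frame."""

    point_id: str
    decision: str  # "clean" | "artifact"
    distance: float
    threshold: float
    frame: Optional[EmbeddingFrame] = None


@dataclass
class RunResult:
    run_id: int
    records: List[dict] = field(default_factory=list)
    rejections: List[dict] = field(default_factory=list)
    covariances: List[np.ndarray] = field(default_factory=list)
    labels: List[str] = field(default_factory=list)
    distance_matrix: Optional[DistanceMatrix] = None
    frames: List[EmbeddingFrame] = field(default_factory=list)
    class_states: Dict[str, ClassState] = field(default_factory=dict)
    class_dispersions: Dict[str, float] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


@dataclass
class SessionResult:
    config: SessionConfig
    runs: List[RunResult] = field(default_factory=list)
    events: List[dict] = field(default_factory=list)
    potato: Optional[PotatoState] = None
    truncated: bool = False


class OnlineBandpass:
    """Causal Butterworth band-pass with carried state (one filter path).

    State is carried across the contiguous segments of a trial and reset at
    trial starts (the inter-trial signal is not streamed).
    """

    def __init__(self, band: Tuple[float, float], fs: float, order: int = 4):
        lo, hi = band
        if not 0.0 < lo < hi < fs / 2.0:
            raise InvalidInputError("band outside (0, Nyquist)")
        self.sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs,
                                 output="sos")
        self._zi: Optional[np.ndarray] = None

    def reset(self) -> None:
        self._zi = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self._zi is None:
            zi0 = signal.sosfilt_zi(self.sos)  # (n_sections, 2)
            self._zi = zi0[:, None, :] * x[:, 0][None, :, None]
        y, self._zi = signal.sosfilt(self.sos, x, axis=1, zi=self._zi)
        return y


def bandpass(
    seg: EEGSegment | np.ndarray,
    band: Tuple[float, float],
    fs: Optional[float] = None,
    mode: str = "offline",
    order: int = 4,
) -> np.ndarray:
    """Band-pass one window: causal ("online") or zero-phase ("offline").

    Online mode filters from rest (no carried state; use
    :class:`OnlineBandpass` for streaming continuity).  Offline mode is the
    zero-phase forward-backward filter used by all after-the-fact analyses.
    """
    if isinstance(seg, EEGSegment):
        x, fs = seg.samples, seg.fs
    else:
        x = np.asarray(seg, dtype=float)
        if fs is None:
            raise InvalidInputError("fs required for raw arrays")
    lo, hi = band
    if not 0.0 < lo < hi < fs / 2.0:
        raise InvalidInputError("band outside (0, Nyquist)")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    if x.shape[1] < 3 * (2 * order + 1):
        raise InvalidInputError("segment too short for the filter order")
    if mode == "online":
        return signal.sosfilt(sos, x, axis=1)
    if mode == "offline":
        return signal.sosfiltfilt(sos, x, axis=1)
    raise InvalidInputError(f"unknown filter mode {mode!r}")


def advanced_protocol_band(
    cfg: SessionConfig,
    session_index: int,
    subject_band: Optional[Tuple[float, float]] = None,
) -> Tuple[float, float]:
    """Feedback band per session: broadband for sessions 1-2, then the
    subject-specific 4-Hz band selected from the first two sessions."""
    if session_index < 1:
        raise InvalidInputError("session_index starts at 1")
    if session_index <= 2:
        return BROADBAND
    if subject_band is None:
        raise InvalidInputError(
            "subject_band required for sessions >= 3 (run band selection first)"
        )
    return tuple(subject_band)


class FeedbackEngine:
    """Streaming state machine implementing the online protocol."""

    def __init__(self, cfg: SessionConfig):
        self.cfg = cfg
        self.potato: Optional[PotatoState] = None
        self._potato_path = OnlineBandpass(cfg.potato_band, cfg.fs, cfg.filter_order)
        self._feedback_path = OnlineBandpass(cfg.feedback_band, cfg.fs,
                                             cfg.filter_order)
        self._run: Optional[RunResult] = None
        self._dm: Optional[DistanceMatrix] = None
        self._class_states: Dict[str, ClassState] = {}
        self._prev_frame: Optional[EmbeddingFrame] = None
        self._frame_index = 0
        self.events: List[dict] = []

    # -- lifecycle -----------------------------------------------------
    def initialize(self, baseline: List[EEGSegment]) -> None:
        """Build the Potato from the resting baseline.

        The 10-s baseline is filtered through the same causal 1-30 Hz path
        the online segments will see (state carried across the contiguous
        baseline windows), so baseline and online covariances are
        comparable.
        """
        self._potato_path.reset()
        covs = [
            estimate_covariance(
                self._potato_path(seg.samples), shrinkage=self.cfg.shrinkage
            )
            for seg in baseline
        ]
        self.potato = initialize_potato(
            covs, z=self.cfg.potato_z, w=self.cfg.potato_w,
            alpha_ref=self.cfg.potato_alpha_ref,
        )

    def start_run(self, run_id: int) -> None:
        """Reset points, frames and class means; the Potato persists."""
        self._run = RunResult(run_id=run_id)
        self._dm = DistanceMatrix()
        self._class_states = {}
        self._prev_frame = None
        self._frame_index = 0

    def start_trial(self) -> None:
        self._potato_path.reset()
        self._feedback_path.reset()

    def finish_run(self) -> RunResult:
        run = self._run
        if run is None:
            raise InvalidInputError("no run in progress")
        run.distance_matrix = self._dm
        run.class_states = dict(self._class_states)
        for label, state in self._class_states.items():
            covs = [c for c, l in zip(run.covariances, run.labels) if l == label]
            if covs:
                run.class_dispersions[label] = mean_absolute_deviation(
                    covs, state.mean
                )
        self._run = None
        return run

    # -- per-segment processing ----------------------------------------
    def process_segment(self, seg: EEGSegment) -> FeedbackUpdate:
        """Gate, accumulate, embed: one feedback update per clean segment."""
        if self.potato is None:
            raise InvalidInputError("engine not initialized from a baseline")
        if self._run is None:
            raise InvalidInputError("no run in progress (call start_run)")
        if seg.label not in ("left", "right"):
            raise InvalidInputError(f"unknown MI label {seg.label!r}")

        point_id = f"r{seg.run_id}t{seg.trial_id}s{seg.segment_index}"
        x_potato = self._potato_path(seg.samples)
        x_feedback = self._feedback_path(seg.samples)
        P_potato = estimate_covariance(x_potato, shrinkage=self.cfg.shrinkage)
        is_artifact, dist = classify_segment(self.potato, P_potato)
        threshold = self.potato.threshold
        event = {
            "run": seg.run_id, "trial": seg.trial_id,
            "segment": seg.segment_index, "label": seg.label,
            "distance": dist, "threshold": threshold,
            "decision": "artifact" if is_artifact else "clean",
        }
        self.events.append(event)

        if is_artifact:
            self.potato = replace(self.potato,
                                  n_rejected=self.potato.n_rejected + 1)
            self._run.rejections.append(event)
            return FeedbackUpdate(point_id=point_id, decision="artifact",
                                  distance=dist, threshold=threshold)

        P = estimate_covariance(x_feedback, shrinkage=self.cfg.shrinkage)
        self.potato = update_potato(self.potato, P_potato, distance=dist)

        dists = [riemannian_distance(P, Q) for Q in self._run.covariances]
        self._dm.append_point(point_id, dists)
        self._run.covariances.append(P)
        self._run.labels.append(seg.label)
        self._run.records.append({**event, "point_id": point_id})

        state = self._class_states.get(seg.label)
        if state is None:
            self._class_states[seg.label] = ClassState(mean=P.copy(), count=1)
        else:
            self._class_states[seg.label] = incremental_mean_update(state, P)

        frame = self._build_frame()
        self._run.frames.append(frame.slim())
        return FeedbackUpdate(point_id=point_id, decision="clean",
                              distance=dist, threshold=threshold, frame=frame)

    def _build_frame(self) -> EmbeddingFrame:
        """Re-embed all points plus the two class-mean pseudo-points."""
        n_real = self._dm.n_points
        idx = self._frame_index
        self._frame_index += 1
        have_both = all(lbl in self._class_states for lbl in ("left", "right"))
        if not have_both or n_real < 3:
            frame = embed(self._dm, epsilon=self.cfg.epsilon,
                          n_real_points=0 if not have_both else n_real,
                          frame_index=idx, keep_matrices=False)
            return frame
        means = [self._class_states["left"].mean,
                 self._class_states["right"].mean]
        rows = np.array([
            [riemannian_distance(M, Q) for Q in self._run.covariances]
            for M in means
        ])
        cross = np.zeros((2, 2))
        cross[0, 1] = cross[1, 0] = riemannian_distance(means[0], means[1])
        dm_ext = self._dm.with_extra_points(list(MEAN_POINT_IDS), rows, cross)
        frame = embed(dm_ext, epsilon=self.cfg.epsilon, n_real_points=n_real,
                      frame_index=idx, keep_matrices=False)
        if self._prev_frame is not None and not frame.warm_up \
                and not self._prev_frame.warm_up:
            frame = anchor_signs(self._prev_frame, frame, ANCHOR_ID)
        if not frame.warm_up:
            self._prev_frame = frame
        return frame


def run_session(source: Session, cfg: Optional[SessionConfig] = None) -> SessionResult:
    """Consume a session stream: baseline -> Potato init, then all runs.

    Returns the complete per-run histories; if the stream ends mid-trial a
    truncated-run warning flag is set and partial results returned.
    """
    if cfg is None:
        cfg = SessionConfig()
    engine = FeedbackEngine(cfg)
    engine.initialize(source.baseline)
    result = SessionResult(config=cfg)
    truncated = False
    for run in source.runs:
        engine.start_run(run.run_id)
        for trial in run.trials:
            engine.start_trial()
            if len(trial.segments) < cfg.segments_per_trial:
                truncated = True
            for seg in trial.segments:
                engine.process_segment(seg)
        result.runs.append(engine.finish_run())
    result.events = engine.events
    result.potato = engine.potato
    result.truncated = truncated
    return result
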