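"""Synthetic sensorimotor-rhythm (SMR) motor-imagery EEG sessions.

The generator emulates the physiology the feedback protocol assumes: a
band-limited mu rhythm (default 11 Hz) riding on spatially mixed 1/f
background noise over ten sensorimotor electrodes, with event-related
desynchronization (ERD) — a multiplicative attenuation of the rhythm on the
hemisphere contralateral to the imagined hand — and sporadic high-amplitude
broadband artifacts.  Sessions follow the training protocol's timing: a
10-s resting baseline, then runs of 40 cued trials (balanced left/right),
each contributing four 1-s motor-imagery segments.

Every pipeline stage is testable against the generator's ground truth
(labels, artifact flags, the ERD effect size g and rhythm frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, List, Optional

import numpy as np

from .geometry import EEGSegment, InvalidInputError

__all__ = [
    "FEEDBACK_CHANNELS",
    "LEFT_HEMISPHERE",
    "RIGHT_HEMISPHERE",
    "GeneratorConfig",
    "Trial",
    "Run",
    "Session",
    "generate_segment",
    "inject_artifact",
    "generate_session",
]

# the ten feedback electrodes, symmetric over the sensorimotor strip
FEEDBACK_CHANNELS = ["FC3", "FC4", "C5", "C3", "C1", "C2", "C4", "C6", "CP3", "CP4"]
# odd indices = left hemisphere, even = right (10-20 convention)
LEFT_HEMISPHERE = {"FC3", "C5", "C3", "C1", "CP3"}
RIGHT_HEMISPHERE = {"FC4", "C2", "C4", "C6", "CP4"}

# focal mu-rhythm topography: the source peaks over the hand area (C3/C4)
# and falls off toward neighbouring electrodes.  A spatially flat rhythm
# would be annihilated exactly by a Laplacian derivation, which no real
# scalp rhythm is.
RHYTHM_TOPOGRAPHY = {
    "C3": 1.0, "C4": 1.0,
    "FC3": 0.6, "C5": 0.6, "C1": 0.6, "CP3": 0.6,
    "FC4": 0.6, "C2": 0.6, "C6": 0.6, "CP4": 0.6,
}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic session generator.

    ``erd_effect`` g in [0, 1) is the fractional rhythm-amplitude
    attenuation on the hemisphere contralateral to the imagined hand;
    g = 0 makes the two classes statistically exchangeable.
    ``artifact_gain`` scales the broadband transient relative to the clean
    per-channel RMS.
    """

    n_channels: int = 10
    channel_names: List[str] = field(default_factory=lambda: list(FEEDBACK_CHANNELS))
    fs: float = 250.0
    rhythm_freq: float = 11.0
    rhythm_amplitude: float = 0.8
    erd_effect: float = 0.4
    noise_scale: float = 1.0
    mixing_strength: float = 0.3
    artifact_rate: float = 0.0
    artifact_gain: float = 10.0
    trials_per_run: int = 40
    runs_per_session: int = 5
    segments_per_trial: int = 4
    baseline_segments: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_effect < 1.0:
            raise InvalidInputError("erd_effect g must lie in [0, 1)")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise InvalidInputError("artifact_rate must lie in [0, 1)")
        if self.artifact_gain <= 1.0:
            raise InvalidInputError("artifact_gain must exceed 1")
        if self.rhythm_freq >= self.fs / 2:
            raise InvalidInputError("rhythm frequency must be below Nyquist")
        if len(self.channel_names) != self.n_channels:
            raise InvalidInputError("channel_names length must equal n_channels")
        if self.trials_per_run % 2 != 0:
            raise InvalidInputError("trials_per_run must be even (balanced cues)")


@dataclass
class Trial:
    label: str
    segments: List[EEGSegment]


@dataclass
class Run:
    run_id: int
    trials: List[Trial]


@dataclass
class Session:
    """Baseline plus runs of labeled trials, consumable by the engine."""

    config: GeneratorConfig
    baseline: List[EEGSegment]
    runs: List[Run]

    def mi_segments(self) -> Iterator[EEGSegment]:
        for run in self.runs:
            for trial in run.trials:
                yield from trial.segments


def _pink_noise(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    scale = 1.0 / np.sqrt(np.maximum(freqs * n_samples, 1.0))
    x = np.fft.irfft(spec * scale, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _mixing_matrix(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Fixed spatial mixing: identity plus a small random coupling."""
    A = np.eye(cfg.n_channels) + cfg.mixing_strength * rng.standard_normal(
        (cfg.n_channels, cfg.n_channels)
    ) / np.sqrt(cfg.n_channels)
    return A


def _rhythm_gains(label: str, cfg: GeneratorConfig) -> np.ndarray:
    """Per-channel rhythm amplitude: focal topography, contralateral ERD."""
    g = cfg.erd_effect
    gains = np.array([
        cfg.rhythm_amplitude * RHYTHM_TOPOGRAPHY.get(ch, 1.0)
        for ch in cfg.channel_names
    ])
    if label == "left":
        attenuated = RIGHT_HEMISPHERE
    elif label == "right":
        attenuated = LEFT_HEMISPHERE
    else:  # rest: full rhythm on both hemispheres
        attenuated = set()
    for i, ch in enumerate(cfg.channel_names):
        if ch in attenuated:
            gains[i] *= 1.0 - g
    return gains


def generate_segment(
    label: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    mixing: Optional[np.ndarray] = None,
    duration: float = 1.0,
    **meta,
) -> EEGSegment:
    """One labeled EEG window: mixed 1/f background + lateralised rhythm.

    The rhythm is a sinusoid at ``rhythm_freq`` with a shared random phase
    per segment, mild per-segment amplitude variability, and per-channel
    gains attenuated by (1 - g) contralaterally to the imagined hand.
    Reproducible given the same rng state.
    """
    if label not in ("left", "right", "rest"):
        raise InvalidInputError(f"unknown label {label!r}")
    n_t = int(round(duration * cfg.fs))
    if mixing is None:
        mixing = np.eye(cfg.n_channels)
    sources = np.stack([_pink_noise(n_t, rng) for _ in range(cfg.n_channels)])
    background = cfg.noise_scale * (mixing @ sources)
    t = np.arange(n_t) / cfg.fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    amp_jitter = np.exp(0.1 * rng.standard_normal())
    wave = np.sin(2.0 * np.pi * cfg.rhythm_freq * t + phase)
    gains = _rhythm_gains(label, cfg) * amp_jitter
    samples = background + gains[:, None] * wave[None, :]
    return EEGSegment(samples=samples, fs=cfg.fs, label=label,
                      is_artifact=False, **meta)


def inject_artifact(
    seg: EEGSegment,
    gain: float,
    rng: np.random.Generator,
) -> EEGSegment:
    """Superimpose a broadband high-amplitude transient; flags ground truth.

    The transient is Hann-enveloped white noise scaled to ``gain`` times the
    clean per-channel RMS, across all channels — so at gain 10 the segment
    variance is roughly 1 + 10^2 * mean(hann^2) ~ 38x the clean variance.
    """
    if gain <= 1.0:
        raise InvalidInputError("artifact gain must exceed 1")
    x = seg.samples
    n_ch, n_t = x.shape
    rms = x.std(axis=1, keepdims=True)
    envelope = np.hanning(n_t)[None, :]
    transient = gain * rms * envelope * rng.standard_normal((n_ch, n_t))
    return replace(seg, samples=x + transient, is_artifact=True)


def _cue_order(cfg: GeneratorConfig, rng: np.random.Generator) -> List[str]:
    """Balanced pseudo-random left/right cue sequence for one run."""
    half = cfg.trials_per_run // 2
    cues = ["left"] * half + ["right"] * half
    rng.shuffle(cues)
    return cues


def generate_session(cfg: GeneratorConfig) -> Session:
    """Full labeled session: baseline then runs of balanced cued trials.

    One shared RNG (from ``cfg.seed``) drives everything, so the same
    config reproduces the identical session bit-for-bit.  Baseline
    segments are clean resting EEG; each MI segment is independently
    replaced by an artifact-bearing one with probability ``artifact_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    mixing = _mixing_matrix(cfg, rng)
    baseline = [
        generate_segment("rest", cfg, rng, mixing=mixing,
                         run_id=-1, trial_id=-1, segment_index=i)
        for i in range(cfg.baseline_segments)
    ]
    runs: List[Run] = []
    for r in range(cfg.runs_per_session):
        cues = _cue_order(cfg, rng)
        trials: List[Trial] = []
        for j, cue in enumerate(cues):
            segs: List[EEGSegment] = []
            for k in range(cfg.segments_per_trial):
                seg = generate_segment(cue, cfg, rng, mixing=mixing,
                                       run_id=r, trial_id=j, segment_index=k)
                if cfg.artifact_rate > 0 and rng.uniform() < cfg.artifact_rate:
                    seg = inject_artifact(seg, cfg.artifact_gain, rng)
                segs.append(seg)
            trials.append(Trial(label=cue, segments=segs))
        runs.append(Run(run_id=r, trials=trials))
    return Session(config=cfg, baseline=baseline, runs=runs)
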