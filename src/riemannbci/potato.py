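"""Riemannian Potato: online multivariate EEG artifact gate.

A reference point on the SPD manifold is initialised as the Fréchet mean of
the resting-baseline covariances; any incoming segment whose geodesic
distance to the reference exceeds an adaptive threshold ``mu + z * sigma``
is rejected as an artifact.  Clean segments mildly adapt both the reference
(geodesic step of 1/alpha_ref) and the distance statistics (exponential
moving mean/variance with rate w).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .geometry import (
    ClassState,
    InvalidInputError,
    incremental_mean_update,
    riemannian_distance,
    riemannian_mean,
)

__all__ = [
    "PotatoState",
    "PotatoContractError",
    "initialize_potato",
    "classify_segment",
    "update_potato",
]


class PotatoContractError(RuntimeError):
    """update_potato was called with a segment the gate flagged as artifact."""


@dataclass
class PotatoState:
    """Adaptive artifact-gate state.

    ``reference`` is the Potato centre (SPD), ``mu``/``sigma`` the running
    mean and spread of clean distances, ``z`` the threshold multiplier,
    ``w`` the statistic adaptation rate and ``alpha_ref`` the reference
    adaptation speed.  The rejection threshold is always recomputed as
    ``mu + z * sigma``, never cached.
    """

    reference: np.ndarray
    mu: float
    sigma: float
    z: float = 2.5
    w: float = 0.01
    alpha_ref: float = 100.0
    n_clean: int = 0
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidInputError("sigma must be >= 0")
        if self.n_clean < 0 or self.n_rejected < 0:
            raise InvalidInputError("counters must be non-negative")

    @property
    def threshold(self) -> float:
        return self.mu + self.z * self.sigma


def initialize_potato(
    baseline_covs: Sequence[np.ndarray],
    z: float = 2.5,
    w: float = 0.01,
    alpha_ref: float = 100.0,
) -> PotatoState:
    """Initialise the gate from resting-baseline covariances.

    The reference is the batch Fréchet mean of the baseline (the protocol
    uses ten 1-s covariances from a 10-s resting recording, 1-30 Hz
    filtered); ``mu`` and ``sigma`` are the mean and standard deviation of
    the baseline distances to that reference.
    """
    if len(baseline_covs) < 2:
        raise InvalidInputError("need at least 2 baseline covariances")
    ref_state = riemannian_mean(list(baseline_covs))
    ref = ref_state.mean
    dists = np.array([riemannian_distance(P, ref) for P in baseline_covs])
    mu = float(dists.mean())
    sigma = float(dists.std(ddof=0))
    if sigma == 0.0:
        warnings.warn(
            "degenerate baseline (all distances identical): sigma = 0, "
            "the gate starts maximally strict",
            stacklevel=2,
        )
    return PotatoState(reference=ref, mu=mu, sigma=sigma, z=z, w=w, alpha_ref=alpha_ref)


def classify_segment(state: PotatoState, P: np.ndarray) -> tuple[bool, float]:
    """Gate one covariance; returns ``(is_artifact, distance)``.

    Pure function of the state: artifact iff the geodesic distance to the
    reference strictly exceeds ``mu + z * sigma``.  The state is untouched.
    """
    P = np.asarray(P, dtype=float)
    if P.shape != state.reference.shape:
        raise InvalidInputError("dimension mismatch with Potato reference")
    d = riemannian_distance(P, state.reference)
    return d > state.threshold, d


def update_potato(
    state: PotatoState,
    P_clean: np.ndarray,
    distance: float | None = None,
) -> PotatoState:
    """Absorb one clean covariance into the gate.

    The reference moves one geodesic step of length ``1/alpha_ref`` toward
    the segment; the statistics follow exponential updates with rate ``w``
    (mu first, then the variance using the updated mu, then the square
    root).  Must only be called with segments the gate classified clean.
    """
    is_art, d = classify_segment(state, P_clean)
    if distance is not None:
        d = distance
    if is_art:
        raise PotatoContractError(
            "update_potato called with a segment classified as artifact"
        )
    ref_state = ClassState(mean=state.reference, count=max(state.n_clean, 1))
    new_ref = incremental_mean_update(ref_state, P_clean, alpha=state.alpha_ref).mean
    w = state.w
    mu_new = (1.0 - w) * state.mu + w * d
    var_new = (1.0 - w) * state.sigma**2 + w * (d - mu_new) ** 2
    sigma_new = float(np.sqrt(max(var_new, 0.0)))
    return replace(
        state,
        reference=new_ref,
        mu=mu_new,
        sigma=sigma_new,
        n_clean=state.n_clean + 1,
    )
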