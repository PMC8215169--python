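"""Riemannian geometry primitives on symmetric positive-definite (SPD) matrices.

The spatial covariance of a band-limited multi-channel EEG window is an SPD
matrix, a point on the curved manifold :math:`\\mathcal{P}(n)`.  Under the
affine-invariant metric the geodesic distance between two points is

.. math:: \\delta(P_1, P_2) = \\|\\log(P_1^{-1/2} P_2 P_1^{-1/2})\\|_F
          = \\Big(\\sum_i \\log^2 \\lambda_i\\Big)^{1/2}

with :math:`\\lambda_i` the eigenvalues of :math:`P_1^{-1} P_2`.  The Fréchet
(Riemannian) mean of a set of SPD matrices minimises the summed squared
geodesic distances, and the mean absolute deviation is the average geodesic
distance to that mean.  These primitives back every stage of the feedback
pipeline: artifact gating, class prototypes, feedback embedding and the
minimum-distance-to-mean classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EEGSegment",
    "ClassState",
    "InvalidInputError",
    "RankDeficiencyError",
    "ConvergenceError",
    "validate_spd",
    "estimate_covariance",
    "riemannian_distance",
    "riemannian_mean",
    "incremental_mean_update",
    "mean_absolute_deviation",
    "geodesic_point",
    "spd_logm",
    "spd_expm",
    "spd_power",
    "spd_sqrtm",
    "spd_invsqrtm",
]

# absolute eigenvalue floor used by all matrix functions to absorb round-off
EIG_FLOOR = 1e-12


class InvalidInputError(ValueError):
    """Raised for non-finite or structurally invalid inputs."""


class RankDeficiencyError(ValueError):
    """Covariance estimate is not positive definite.

    Carries the offending matrix in :attr:`matrix`; raising sites advise
    using ``shrinkage > 0`` to restore positivity.
    """

    def __init__(self, message: str, matrix: np.ndarray):
        super().__init__(message)
        self.matrix = matrix


class ConvergenceError(RuntimeError):
    """Fréchet-mean iteration did not converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class EEGSegment:
    """One 1-s multi-channel EEG window with protocol metadata.

    ``samples`` is channels x time in microvolts.  ``label`` is one of
    ``"left"``, ``"right"``, ``"rest"``.  ``clean`` is set by the artifact
    gate; ``is_artifact`` is the generator's ground truth (None for real
    data).
    """

    samples: np.ndarray
    fs: float = 250.0
    label: str = "rest"
    run_id: int = 0
    trial_id: int = 0
    segment_index: int = 0
    clean: Optional[bool] = None
    is_artifact: Optional[bool] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InvalidInputError("samples must be a 2-D channels x time array")
        n_ch, n_t = self.samples.shape
        if n_ch < 2:
            raise InvalidInputError("need at least 2 channels")
        if n_t < n_ch:
            raise InvalidInputError("need at least as many samples as channels")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class ClassState:
    """Streaming state of one class prototype on the SPD manifold.

    ``mean`` is the current Fréchet-mean estimate, ``count`` the number of
    matrices absorbed, ``dispersion`` the mean absolute deviation (0 while
    count <= 1), and ``step_exponent`` the adaptation speed alpha used by
    geodesic updates (None means "use the running count").
    """

    mean: np.ndarray
    count: int = 1
    dispersion: float = 0.0
    step_exponent: Optional[float] = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise InvalidInputError("count must be >= 0")
        if self.dispersion < 0:
            raise InvalidInputError("dispersion must be >= 0")
        if self.count <= 1 and self.dispersion != 0.0:
            raise InvalidInputError("dispersion must be 0 for count <= 1")


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return 0.5 * (P + P.T)


def validate_spd(P: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Check symmetry (relative tolerance) and positive-definiteness.

    Returns the symmetrised matrix; raises :class:`InvalidInputError` on
    failure.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise InvalidInputError("SPD matrix must be square")
    if not np.all(np.isfinite(P)):
        raise InvalidInputError("SPD matrix contains non-finite entries")
    scale = max(np.abs(P).max(), 1.0)
    if np.abs(P - P.T).max() > rtol * scale:
        raise InvalidInputError("matrix is not symmetric within tolerance")
    Ps = _symmetrize(P)
    w = np.linalg.eigvalsh(Ps)
    if w[0] <= 0:
        raise InvalidInputError(
            f"matrix is not positive definite (min eigenvalue {w[0]:.3e})"
        )
    return Ps


def _eigh_floor(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, V = np.linalg.eigh(_symmetrize(np.asarray(P, dtype=float)))
    return np.maximum(w, EIG_FLOOR), V


def spd_power(P: np.ndarray, p: float) -> np.ndarray:
    """Matrix power of an SPD matrix via eigendecomposition."""
    w, V = _eigh_floor(P)
    return _symmetrize((V * w**p) @ V.T)


def spd_sqrtm(P: np.ndarray) -> np.ndarray:
    return spd_power(P, 0.5)


def spd_invsqrtm(P: np.ndarray) -> np.ndarray:
    return spd_power(P, -0.5)


def spd_logm(P: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (symmetric result)."""
    w, V = _eigh_floor(P)
    return _symmetrize((V * np.log(w)) @ V.T)


def spd_expm(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (SPD result)."""
    S = np.asarray(S, dtype=float)
    w, V = np.linalg.eigh(_symmetrize(S))
    return _symmetrize((V * np.exp(w)) @ V.T)


def estimate_covariance(
    seg: EEGSegment | np.ndarray,
    demean: bool = False,
    shrinkage: float = 0.0,
) -> np.ndarray:
    """Sample spatial covariance ``X X^T / (T - 1)`` of one EEG window.

    Parameters
    ----------
    seg
        Segment (or raw channels x time array) with T > 1 samples.
    demean
        Subtract each channel's mean first.  Off by default: band-passed
        EEG is near zero-mean and the plain cross-product is the protocol's
        definition.
    shrinkage
        Convex blend with the trace-scaled identity,
        ``(1 - s) * C + s * (tr(C)/n) * I``, guarding against
        ill-conditioned 10x10 estimates from short windows.

    Raises
    ------
    RankDeficiencyError
        If the result is not positive definite (rank-deficient window with
        ``shrinkage == 0``); the error carries the computed matrix.
    """
    X = seg.samples if isinstance(seg, EEGSegment) else np.asarray(seg, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError("expected a 2-D channels x time array")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("segment contains non-finite values")
    n, T = X.shape
    if T <= 1:
        raise InvalidInputError("need more than one time sample")
    if not 0.0 <= shrinkage <= 1.0:
        raise InvalidInputError("shrinkage must lie in [0, 1]")
    if demean:
        X = X - X.mean(axis=1, keepdims=True)
    C = (X @ X.T) / (T - 1)
    if shrinkage > 0.0:
        C = (1.0 - shrinkage) * C + shrinkage * (np.trace(C) / n) * np.eye(n)
    C = _symmetrize(C)
    w = np.linalg.eigvalsh(C)
    if w[0] <= 0:
        raise RankDeficiencyError(
            "covariance is rank-deficient; increase shrinkage (> 0) "
            f"(min eigenvalue {w[0]:.3e})",
            C,
        )
    return C


def riemannian_distance(P1: np.ndarray, P2: np.ndarray) -> float:
    """Affine-invariant geodesic distance between two SPD matrices.

    Computed from the eigenvalues of the symmetric form
    ``P1^{-1/2} P2 P1^{-1/2}`` (same spectrum as ``P1^{-1} P2`` but
    numerically stabler).
    """
    P1 = np.asarray(P1, dtype=float)
    P2 = np.asarray(P2, dtype=float)
    if P1.shape != P2.shape:
        raise InvalidInputError("dimension mismatch between SPD matrices")
    isq = spd_invsqrtm(P1)
    M = _symmetrize(isq @ P2 @ isq)
    w = np.maximum(np.linalg.eigvalsh(M), EIG_FLOOR)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def geodesic_point(P1: np.ndarray, P2: np.ndarray, t: float) -> np.ndarray:
    """Point at fraction ``t`` along the geodesic from P1 to P2.

    ``P1^{1/2} (P1^{-1/2} P2 P1^{-1/2})^t P1^{1/2}``; t=0 gives P1, t=1
    gives P2.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("geodesic parameter t must lie in [0, 1]")
    sq = spd_sqrtm(P1)
    isq = spd_invsqrtm(P1)
    inner = spd_power(_symmetrize(isq @ P2 @ isq), t)
    return _symmetrize(sq @ inner @ sq)


def riemannian_mean(
    Ps: Sequence[np.ndarray],
    tol: float = 1e-9,
    max_iter: int = 100,
) -> ClassState:
    """Fréchet mean of a set of SPD matrices by tangent-space descent.

    Iterates: project all matrices to the tangent space at the current
    estimate, average the logs, exponentiate the average back (unit step),
    until the Frobenius norm of the tangent gradient falls below ``tol``.
    Returns a :class:`ClassState` whose ``dispersion`` is the mean absolute
    deviation about the converged mean.
    """
    if len(Ps) == 0:
        raise InvalidInputError("need at least one SPD matrix")
    mats = [np.asarray(P, dtype=float) for P in Ps]
    dim = mats[0].shape
    for P in mats:
        if P.shape != dim:
            raise InvalidInputError("SPD matrices must share a common dimension")
    if len(mats) == 1:
        return ClassState(mean=mats[0].copy(), count=1, dispersion=0.0)

    M = _symmetrize(np.mean(mats, axis=0))  # arithmetic-mean initialisation
    for _ in range(max_iter):
        sq = spd_sqrtm(M)
        isq = spd_invsqrtm(M)
        S = np.zeros_like(M)
        for P in mats:
            S += spd_logm(_symmetrize(isq @ P @ isq))
        S /= len(mats)
        grad_norm = float(np.linalg.norm(S, "fro"))
        if grad_norm < tol:
            break
        M = _symmetrize(sq @ spd_expm(S) @ sq)
    else:
        raise ConvergenceError(
            f"Fréchet mean did not converge in {max_iter} iterations "
            f"(gradient norm {grad_norm:.3e})",
            M,
        )
    disp = mean_absolute_deviation(mats, M)
    return ClassState(mean=M, count=len(mats), dispersion=disp)


def incremental_mean_update(
    state: ClassState,
    P: np.ndarray,
    alpha: Optional[float] = None,
) -> ClassState:
    """Move the running mean one geodesic step of length 1/alpha toward P.

    ``new_mean = M^{1/2} (M^{-1/2} P M^{-1/2})^{1/alpha} M^{1/2}``.  With
    ``alpha`` equal to the running count (the default when both ``alpha``
    and ``state.step_exponent`` are None) this is a uniform-weight
    streaming approximation of the batch Fréchet mean; a fixed alpha (e.g.
    100 for the artifact-gate reference) gives a slowly adapting prototype.
    """
    if alpha is None:
        alpha = state.step_exponent
    if alpha is None:
        alpha = state.count + 1
    if alpha <= 0:
        raise InvalidInputError("adaptation speed alpha must be > 0")
    P = np.asarray(P, dtype=float)
    if P.shape != state.mean.shape:
        raise InvalidInputError("dimension mismatch in incremental mean update")
    t = min(1.0 / alpha, 1.0)
    new_mean = geodesic_point(state.mean, P, t)
    return replace(state, mean=new_mean, count=state.count + 1)


def mean_absolute_deviation(
    Ps: Sequence[np.ndarray],
    mean: np.ndarray,
) -> float:
    """Average geodesic distance of each matrix to the given mean."""
    if len(Ps) == 0:
        raise InvalidInputError("need at least one SPD matrix")
    return float(np.mean([riemannian_distance(P, mean) for P in Ps]))
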