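"""Diffusion-map embedding of an accumulating pairwise-distance matrix.

Each clean feedback segment adds one row to a symmetric matrix of pairwise
geodesic distances.  The matrix is converted to 2-D screen coordinates by a
diffusion map: Gaussian kernel K_ij = exp(-d_ij^2 / eps), symmetric
normalisation K_norm = D^{-1/2} K D^{-1/2} with D the diagonal of row sums,
eigendecomposition, and coordinates Y_i = (lambda_1 phi_1i, ...,
lambda_d phi_di) from the d dominant non-trivial eigenpairs (the stationary
lambda_0 = 1 pair is skipped).  Because eigenvectors are defined only up to
sign, consecutive frames are aligned by forcing a designated anchor point
(a class-mean pseudo-point) to keep a constant coordinate sign per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "DistanceMatrix",
    "EmbeddingFrame",
    "gaussian_kernel",
    "normalize_kernel",
    "diffusion_coordinates",
    "embed",
    "anchor_signs",
]

# below this many points the projection is too variable to be meaningful
WARMUP_MIN_POINTS = 3


class DistanceMatrix:
    """Growable N x N symmetric nonnegative distance matrix with point ids.

    Rows are appended in O(N) amortised time via a capacity-doubling
    buffer.  ``point_ids`` may include pseudo-points (the two class means).
    """

    def __init__(self, point_ids: Optional[Sequence[str]] = None,
                 values: Optional[np.ndarray] = None):
        if point_ids is None:
            point_ids = []
        self.point_ids: List[str] = list(point_ids)
        n = len(self.point_ids)
        if values is None:
            if n != 0:
                raise ValueError("point_ids given without values")
            cap = 8
            self._buf = np.zeros((cap, cap))
            self._n = 0
        else:
            values = np.asarray(values, dtype=float)
            if values.shape != (n, n):
                raise ValueError("values shape does not match point_ids")
            if np.any(values < 0):
                raise ValueError("distances must be nonnegative")
            if not np.allclose(values, values.T):
                raise ValueError("distance matrix must be symmetric")
            cap = max(8, n)
            self._buf = np.zeros((cap, cap))
            self._buf[:n, :n] = values
            self._n = n

    @property
    def n_points(self) -> int:
        return self._n

    @property
    def values(self) -> np.ndarray:
        return self._buf[: self._n, : self._n].copy()

    def append_point(self, point_id: str, new_distances: Sequence[float]) -> None:
        """Append one point given its distances to all existing points."""
        d = np.asarray(new_distances, dtype=float)
        if d.shape != (self._n,):
            raise ValueError(
                f"expected {self._n} distances, got {d.shape}"
            )
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        n = self._n
        if n + 1 > self._buf.shape[0]:
            cap = 2 * self._buf.shape[0]
            buf = np.zeros((cap, cap))
            buf[:n, :n] = self._buf[:n, :n]
            self._buf = buf
        self._buf[n, :n] = d
        self._buf[:n, n] = d
        self._buf[n, n] = 0.0
        self.point_ids.append(point_id)
        self._n += 1

    def copy(self) -> "DistanceMatrix":
        return DistanceMatrix(self.point_ids, self.values)

    def with_extra_points(
        self, ids: Sequence[str], rows: np.ndarray, cross: np.ndarray
    ) -> "DistanceMatrix":
        """Return a copy extended by pseudo-points.

        ``rows`` is (k, N) distances from each pseudo-point to the real
        points; ``cross`` is the (k, k) distance matrix among the
        pseudo-points themselves.
        """
        k = len(ids)
        n = self._n
        vals = np.zeros((n + k, n + k))
        vals[:n, :n] = self._buf[:n, :n]
        vals[n:, :n] = rows
        vals[:n, n:] = rows.T
        vals[n:, n:] = cross
        return DistanceMatrix(list(self.point_ids) + list(ids), vals)


@dataclass
class EmbeddingFrame:
    """One feedback update: coordinates plus the spectral quantities behind it.

    ``coordinates`` is N x d; ``anchor_signs`` records the +-1 flips applied
    per axis during anchoring.  ``warm_up`` marks frames with too few real
    points for a stable projection (coordinates all zero).
    """

    point_ids: List[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    epsilon: float
    warm_up: bool = False
    anchor_signs: Optional[np.ndarray] = None
    kernel: Optional[np.ndarray] = None
    normalized_kernel: Optional[np.ndarray] = None
    frame_index: int = 0

    def slim(self) -> "EmbeddingFrame":
        """Copy without the dense kernel matrices (for frame histories)."""
        return replace(self, kernel=None, normalized_kernel=None)


def gaussian_kernel(D: DistanceMatrix | np.ndarray, epsilon: float) -> np.ndarray:
    """K_ij = exp(-d_ij^2 / epsilon); unit diagonal, entries in (0, 1]."""
    if epsilon <= 0:
        raise ValueError("kernel scale epsilon must be > 0")
    vals = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    K = np.exp(-(vals**2) / epsilon)
    np.fill_diagonal(K, 1.0)
    return K


def normalize_kernel(K: np.ndarray) -> np.ndarray:
    """Symmetric normalisation D^{-1/2} K D^{-1/2}, D = diag(row sums)."""
    K = np.asarray(K, dtype=float)
    deg = K.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("kernel has a non-positive row sum")
    inv_sqrt = 1.0 / np.sqrt(deg)
    return K * np.outer(inv_sqrt, inv_sqrt)


def _ordered_eigh(Knorm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs sorted by descending eigenvalue with deterministic ties.

    Within a group of numerically equal eigenvalues, eigenvectors are
    ordered by the index of their first significant component; each
    eigenvector's sign is fixed so its largest-magnitude component is
    positive.
    """
    w, V = np.linalg.eigh(Knorm)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    # deterministic tie-break inside near-degenerate groups
    i = 0
    n = len(w)
    while i < n:
        j = i + 1
        while j < n and abs(w[j] - w[i]) < 1e-12:
            j += 1
        if j - i > 1:
            keys = []
            for k in range(i, j):
                nz = np.nonzero(np.abs(V[:, k]) > 1e-10)[0]
                keys.append(nz[0] if len(nz) else n)
            sub = np.argsort(keys, kind="stable")
            V[:, i:j] = V[:, i:j][:, sub]
        i = j
    for k in range(n):
        m = np.argmax(np.abs(V[:, k]))
        if V[m, k] < 0:
            V[:, k] = -V[:, k]
    return w, V


def diffusion_coordinates(Knorm: np.ndarray, d: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Map points to d dimensions from the dominant non-trivial eigenpairs.

    Returns ``(coordinates, eigenvalues)`` where coordinates[i, k] =
    lambda_{k+1} * phi_{k+1, i}; the stationary lambda_0 = 1 pair is
    skipped.  Requires N >= d + 1 points.
    """
    Knorm = np.asarray(Knorm, dtype=float)
    N = Knorm.shape[0]
    if d < 1:
        raise ValueError("embedding dimension d must be >= 1")
    if N < d + 1:
        raise ValueError(f"need at least {d + 1} points for a {d}-D embedding")
    w, V = _ordered_eigh(Knorm)
    coords = V[:, 1 : d + 1] * w[1 : d + 1]
    return coords, w


def embed(
    D: DistanceMatrix,
    epsilon: float = 20.0,
    d: int = 2,
    n_real_points: Optional[int] = None,
    frame_index: int = 0,
    keep_matrices: bool = True,
) -> EmbeddingFrame:
    """Full pipeline: kernel -> normalisation -> coordinates -> frame.

    ``n_real_points`` counts points that are not class-mean pseudo-points;
    below the warm-up minimum (or when N < d + 1) an all-zero frame flagged
    ``warm_up`` is returned.
    """
    N = D.n_points
    if n_real_points is None:
        n_real_points = N
    if n_real_points < WARMUP_MIN_POINTS or N < d + 1:
        return EmbeddingFrame(
            point_ids=list(D.point_ids),
            coordinates=np.zeros((N, d)),
            eigenvalues=np.zeros(N),
            epsilon=epsilon,
            warm_up=True,
            frame_index=frame_index,
        )
    K = gaussian_kernel(D, epsilon)
    Kn = normalize_kernel(K)
    coords, w = diffusion_coordinates(Kn, d)
    return EmbeddingFrame(
        point_ids=list(D.point_ids),
        coordinates=coords,
        eigenvalues=w,
        epsilon=epsilon,
        kernel=K if keep_matrices else None,
        normalized_kernel=Kn if keep_matrices else None,
        frame_index=frame_index,
    )


def anchor_signs(
    frame_prev: EmbeddingFrame,
    frame_new: EmbeddingFrame,
    anchor_id: str,
) -> EmbeddingFrame:
    """Flip axes of the new frame so the anchor keeps its coordinate signs.

    The eigenvector sign ambiguity makes the projection flip between
    consecutive frames; pinning a designated class-mean pseudo-point's sign
    per axis (sign 0 treated as +) removes the flips for every point.
    """
    if anchor_id not in frame_prev.point_ids or anchor_id not in frame_new.point_ids:
        raise ValueError(f"anchor point {anchor_id!r} missing from a frame")
    ip = frame_prev.point_ids.index(anchor_id)
    inew = frame_new.point_ids.index(anchor_id)
    prev_sign = np.where(frame_prev.coordinates[ip] >= 0, 1.0, -1.0)
    new_sign = np.where(frame_new.coordinates[inew] >= 0, 1.0, -1.0)
    flips = prev_sign * new_sign
    return replace(
        frame_new,
        coordinates=frame_new.coordinates * flips,
        anchor_signs=flips,
    )
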