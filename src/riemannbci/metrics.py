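"""Classifier-independent and classifier-based learning metrics.

ClassDis quantifies the separability of the two motor-imagery classes on
the SPD manifold: the geodesic distance between the class Fréchet means
divided by half the summed class dispersions (a Riemannian Fisher
criterion).  Spatio-spectral discriminancy is the Fisher score
|mu1 - mu2| / (s1^2 + s2^2) of band-power features after a Laplacian
spatial derivation.  The classifier-based metric is fivefold
cross-validated accuracy of the minimum-distance-to-mean (MDM) classifier.
Learning trends across runs are Pearson correlations against the run
index.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    InvalidInputError,
    mean_absolute_deviation,
    riemannian_distance,
    riemannian_mean,
)

__all__ = [
    "DegenerateDispersionError",
    "class_distinctiveness",
    "fisher_score",
    "load_default_montage",
    "laplacian_derivation",
    "psd_features",
    "discriminancy_map",
    "mdm_fit",
    "mdm_predict",
    "crossval_accuracy",
    "learning_trend",
]


class DegenerateDispersionError(ValueError):
    """Class dispersions are all zero; the separability ratio is undefined."""


def class_distinctiveness(
    covsA: Sequence[np.ndarray],
    covsB: Sequence[np.ndarray],
) -> float:
    """ClassDis(A, B) = delta(meanA, meanB) / (0.5 * (sigmaA + sigmaB)).

    Means are batch Fréchet means; dispersions the mean absolute geodesic
    deviations.  Symmetric under relabeling; 0 for identical classes.
    Raises :class:`DegenerateDispersionError` when both dispersions vanish
    rather than returning infinity.
    """
    if len(covsA) < 2 or len(covsB) < 2:
        raise InvalidInputError("each class needs at least 2 covariances")
    stateA = riemannian_mean(list(covsA))
    stateB = riemannian_mean(list(covsB))
    num = riemannian_distance(stateA.mean, stateB.mean)
    denom = 0.5 * (stateA.dispersion + stateB.dispersion)
    if denom <= 1e-12:
        raise DegenerateDispersionError(
            "both class dispersions are zero; ClassDis undefined"
        )
    return num / denom


def fisher_score(
    vals1: Sequence[float],
    vals2: Sequence[float],
    classical: bool = False,
) -> float:
    """Per-feature discriminancy |mu1 - mu2| / (s1^2 + s2^2).

    The default follows the protocol's printed form (absolute mean
    difference over the sum of variances); ``classical=True`` squares the
    numerator (the textbook Fisher criterion).
    """
    v1 = np.asarray(vals1, dtype=float)
    v2 = np.asarray(vals2, dtype=float)
    if v1.size < 2 or v2.size < 2:
        raise InvalidInputError("each class needs at least 2 samples")
    num = abs(v1.mean() - v2.mean())
    if classical:
        num = num**2
    denom = v1.std(ddof=0) ** 2 + v2.std(ddof=0) ** 2
    if denom == 0.0:
        raise DegenerateDispersionError("zero within-class variance")
    return float(num / denom)


def load_default_montage() -> Dict[str, List[str]]:
    """Neighbor table for the ten feedback electrodes (editable JSON)."""
    with resources.files("riemannbci.data").joinpath(
        "laplacian_montage.json"
    ).open() as fh:
        return json.load(fh)


def laplacian_derivation(
    X: np.ndarray,
    channels: Sequence[str],
    montage: Optional[Dict[str, List[str]]] = None,
) -> np.ndarray:
    """Spatial high-pass: each channel minus the mean of its neighbors.

    ``montage`` maps channel name -> list of neighbor names; boundary
    channels use whatever neighbors the table lists.
    """
    if montage is None:
        montage = load_default_montage()
    X = np.asarray(X, dtype=float)
    index = {ch: i for i, ch in enumerate(channels)}
    out = np.empty_like(X)
    for i, ch in enumerate(channels):
        if ch not in montage:
            raise InvalidInputError(f"channel {ch!r} missing from montage")
        nbrs = [n for n in montage[ch] if n in index]
        if not nbrs:
            raise InvalidInputError(f"channel {ch!r} has no neighbors present")
        out[i] = X[i] - np.mean([X[index[n]] for n in nbrs], axis=0)
    return out


def psd_features(
    X: np.ndarray,
    fs: float,
    resolution: float = 2.0,
    window: float = 1.0,
    step: float = 0.0625,
    band: Tuple[float, float] = (8.0, 30.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Sliding-window band-power table.

    Hann-windowed periodogram per ``window``-s window sliding every
    ``step`` s, aggregated into ``resolution``-Hz bins covering ``band``.
    Returns ``(powers, bin_edges)`` with powers shaped
    (n_windows, n_channels, n_bins); the window count is
    floor((len - window) / step) + 1.  Non-integer sample steps (62.5 ms
    at 250 Hz) are handled by rounding each window's start index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n_ch, n_t = X.shape
    win = int(round(window * fs))
    if win > n_t:
        raise InvalidInputError("window longer than the signal")
    n_windows = int(np.floor((n_t - win) / (step * fs))) + 1
    starts = [int(round(k * step * fs)) for k in range(n_windows)]
    taper = np.hanning(win)
    norm = (taper**2).sum() * fs
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    edges = np.arange(band[0], band[1] + resolution / 2, resolution)
    n_bins = len(edges) - 1
    powers = np.zeros((n_windows, n_ch, n_bins))
    for w, s in enumerate(starts):
        seg = X[:, s : s + win] * taper[None, :]
        psd = (np.abs(np.fft.rfft(seg, axis=1)) ** 2) / norm
        for b in range(n_bins):
            sel = (freqs >= edges[b]) & (freqs < edges[b + 1])
            powers[w, :, b] = psd[:, sel].sum(axis=1)
    return powers, edges


def discriminancy_map(
    features: np.ndarray,
    labels: Sequence[str],
    channels: Sequence[str],
    classical: bool = False,
) -> Tuple[pd.DataFrame, pd.Series, float]:
    """Fisher score per (channel, band bin), per-channel and overall means.

    ``features`` is (n_samples, n_channels, n_bins) band powers with one
    class label per sample.  Returns the full (channel x bin) score table,
    the per-channel averages, and the overall average (the scalar
    discriminancy learning metric).
    """
    feats = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise InvalidInputError("exactly two classes required")
    m1 = labels == classes[0]
    m2 = labels == classes[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise InvalidInputError("each class needs at least 2 samples")
    n_ch, n_bins = feats.shape[1], feats.shape[2]
    table = np.zeros((n_ch, n_bins))
    for c in range(n_ch):
        for b in range(n_bins):
            table[c, b] = fisher_score(feats[m1, c, b], feats[m2, c, b],
                                       classical=classical)
    df = pd.DataFrame(table, index=list(channels))
    per_channel = df.mean(axis=1)
    return df, per_channel, float(df.values.mean())


def mdm_fit(
    covs: Sequence[np.ndarray],
    labels: Sequence[str],
) -> Dict[str, np.ndarray]:
    """Fit the minimum-distance-to-mean classifier: one Fréchet mean per class."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise InvalidInputError("need at least two classes to fit MDM")
    means: Dict[str, np.ndarray] = {}
    for cls in classes:
        members = [P for P, l in zip(covs, labels) if l == cls]
        if not members:
            raise InvalidInputError(f"class {cls!r} has no training covariance")
        means[str(cls)] = riemannian_mean(members).mean
    return means


def mdm_predict(means: Dict[str, np.ndarray], P: np.ndarray) -> str:
    """Assign to the class with the nearest Fréchet mean.

    Exact ties break deterministically to the lexicographically first
    label.
    """
    best: Optional[str] = None
    best_d = np.inf
    for cls in sorted(means):
        d = riemannian_distance(P, means[cls])
        if d < best_d:
            best, best_d = cls, d
    return best


def crossval_accuracy(
    covs: Sequence[np.ndarray],
    labels: Sequence[str],
    k: int = 5,
    split: str = "sample",
    trial_ids: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> float:
    """Mean held-out MDM accuracy over k stratified folds.

    ``split="sample"`` assigns individual 1-s covariances to folds (the
    protocol counts 160 samples per run); ``split="trial"`` keeps all
    segments of one trial in the same fold, avoiding within-trial leakage.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n != len(covs):
        raise InvalidInputError("covs and labels length mismatch")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise InvalidInputError("both classes must be present")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    if split == "sample":
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            if len(idx) < k:
                raise InvalidInputError(f"fewer than k samples in class {cls!r}")
            rng.shuffle(idx)
            fold[idx] = np.arange(len(idx)) % k
    elif split == "trial":
        if trial_ids is None:
            raise InvalidInputError("trial split requires trial_ids")
        trial_ids = np.asarray(trial_ids)
        tfold: Dict[int, int] = {}
        for cls in classes:
            tr = np.unique(trial_ids[labels == cls])
            rng.shuffle(tr)
            for j, t in enumerate(tr):
                tfold[int(t)] = j % k
        fold = np.array([tfold[int(t)] for t in trial_ids])
    else:
        raise InvalidInputError(f"unknown split {split!r}")

    accs = []
    for f in range(k):
        test = fold == f
        train = ~test
        if len(np.unique(labels[train])) < 2:
            raise InvalidInputError("a training fold lost a class")
        means = mdm_fit([P for P, m in zip(covs, train) if m], labels[train])
        preds = [mdm_predict(means, P) for P, m in zip(covs, test) if m]
        accs.append(np.mean(preds == labels[test]))
    return float(np.mean(accs))


def learning_trend(values: Sequence[float]) -> Tuple[float, float]:
    """Pearson correlation of a per-run metric against the run index.

    Returns (r, two-sided p from the t distribution); a constant series
    has no defined correlation and raises.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise InvalidInputError("need at least 3 runs for a trend")
    if np.allclose(v, v[0]):
        raise InvalidInputError("constant series: correlation undefined")
    res = stats.pearsonr(np.arange(len(v)), v)
    return float(res.statistic), float(res.pvalue)
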