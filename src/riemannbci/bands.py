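"""Subject-specific frequency-band selection for the advanced protocol.

The 8-30 Hz broadband is decomposed into nineteen overlapping 4-Hz bands
(8-12, 9-13, ..., 26-30 Hz).  For each band, every run's clean
motor-imagery segments are zero-phase filtered, converted to covariances,
and scored by ClassDis; scores are averaged over the runs and the band
with the highest mean is the subject's optimal band for later sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import bandpass
from .geometry import EEGSegment, InvalidInputError, estimate_covariance
from .metrics import DegenerateDispersionError, class_distinctiveness

__all__ = ["BandScore", "enumerate_bands", "select_optimal_band"]


@dataclass
class BandScore:
    band: Tuple[float, float]
    classdis_per_run: List[float]
    mean_classdis: float


def enumerate_bands(
    low: float = 8.0,
    high: float = 30.0,
    width: float = 4.0,
    step: float = 1.0,
) -> List[Tuple[float, float]]:
    """All width-Hz bands stepped by ``step`` whose upper edge stays <= high.

    Defaults give the nineteen bands 8-12 through 26-30 Hz.
    """
    if width > high - low:
        raise InvalidInputError("band width exceeds the available range")
    if step <= 0:
        raise InvalidInputError("step must be > 0")
    bands = []
    lo = low
    while lo + width <= high + 1e-9:
        bands.append((round(lo, 6), round(lo + width, 6)))
        lo += step
    return bands


def select_optimal_band(
    runs: Sequence[Sequence[EEGSegment]],
    bands: Optional[Sequence[Tuple[float, float]]] = None,
    shrinkage: float = 0.01,
    low_confidence_gap: float = 0.05,
) -> Tuple[Tuple[float, float], pd.DataFrame]:
    """Score every band by run-averaged ClassDis; return the argmax band.

    ``runs`` is a list of runs, each a list of labeled (left/right) clean
    segments.  Ties break toward the lower-frequency band.  Degenerate
    per-run scores become missing values excluded from the mean (with a
    warning); a selection whose max-median gap is below
    ``low_confidence_gap`` (relative) is flagged in the returned table's
    attrs.
    """
    if bands is None:
        bands = enumerate_bands()
    if not runs:
        raise InvalidInputError("need at least one run")
    rows = []
    for band in bands:
        per_run: List[float] = []
        for segs in runs:
            covsA = [
                estimate_covariance(bandpass(s, band, mode="offline"),
                                    shrinkage=shrinkage)
                for s in segs if s.label == "left"
            ]
            covsB = [
                estimate_covariance(bandpass(s, band, mode="offline"),
                                    shrinkage=shrinkage)
                for s in segs if s.label == "right"
            ]
            if len(covsA) < 2 or len(covsB) < 2:
                raise InvalidInputError("a run lacks segments of both classes")
            try:
                per_run.append(class_distinctiveness(covsA, covsB))
            except DegenerateDispersionError:
                warnings.warn(
                    f"degenerate dispersion in band {band}; run excluded",
                    stacklevel=2,
                )
                per_run.append(np.nan)
        mean = float(np.nanmean(per_run)) if np.any(np.isfinite(per_run)) else np.nan
        rows.append(BandScore(band=band, classdis_per_run=per_run,
                              mean_classdis=mean))
    table = pd.DataFrame(
        {
            "low": [b.band[0] for b in rows],
            "high": [b.band[1] for b in rows],
            "mean_classdis": [b.mean_classdis for b in rows],
        }
    )
    finite = table["mean_classdis"].to_numpy()
    if not np.any(np.isfinite(finite)):
        raise InvalidInputError("no band produced a finite score")
    best_val = np.nanmax(finite)
    # tie toward the lower-frequency band: first index at the maximum
    best_idx = int(np.flatnonzero(finite == best_val)[0])
    best = rows[best_idx].band
    median = float(np.nanmedian(finite))
    gap = (best_val - median) / best_val if best_val > 0 else 0.0
    table.attrs["low_confidence"] = bool(gap < low_confidence_gap)
    table.attrs["selected_band"] = best
    return best, table
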