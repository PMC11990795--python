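"""Kennard-Stone calibration/prediction partitioning.

The greedy max-min rule: seed with the most distant pair, then repeatedly
add the sample whose minimum Euclidean distance to the already-selected set
is largest. Fully deterministic; every argmax tie is broken by the lowest
row index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .dataio import SpectraSet
from .errors import FitError

__all__ = ["SplitResult", "kennard_stone", "split_dataset"]


@dataclass
class SplitResult:
    calibration_indices: List[int]  # in KS selection order
    prediction_indices: List[int]
    metric: str = "euclidean"


def kennard_stone(X: np.ndarray, n_cal: int) -> SplitResult:
    """Select ``n_cal`` space-filling rows of ``X`` by the max-min rule."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 2 <= n_cal <= n:
        raise FitError(f"n_cal must be in [2, {n}], got {n_cal}")
    D = squareform(pdist(X, metric="euclidean"))
    # seed pair: maximal distance, lexicographically smallest (i, j) on ties
    flat = np.argmax(D)  # row-major argmax -> smallest (i, j) automatically
    i0, j0 = divmod(int(flat), n)
    if i0 > j0:
        i0, j0 = j0, i0
    selected = [i0, j0]
    in_set = np.zeros(n, dtype=bool)
    in_set[[i0, j0]] = True
    min_dist = np.minimum(D[i0], D[j0])
    while len(selected) < n_cal:
        min_dist[in_set] = -np.inf
        nxt = int(np.argmax(min_dist))  # lowest index wins ties
        selected.append(nxt)
        in_set[nxt] = True
        min_dist = np.minimum(min_dist, D[nxt])
    prediction = [i for i in range(n) if not in_set[i]]
    return SplitResult(calibration_indices=selected, prediction_indices=prediction)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_dataset(
    ds: SpectraSet,
    ratio: float = 0.7,
    n_cal: int | None = None,
    standardize: bool = True,
) -> Tuple[SpectraSet, SpectraSet, SplitResult]:
    """Partition a dataset into calibration and prediction subsets.

    Distances are computed on per-column standardized spectra by default
    (Kennard-Stone is scale-sensitive). ``n_cal`` defaults to
    ``round(ratio * n)`` with half-away-from-zero rounding; pass it
    explicitly to pin an exact calibration size.
    """
    if ds.y is None:
        raise FitError("split_dataset requires a response vector y")
    n = ds.n_samples
    if n_cal is None:
        n_cal = _round_half_away(ratio * n)
    n_cal = min(max(n_cal, 2), n)
    if n_cal == n:
        warnings.warn("prediction set is empty (ratio too high)", stacklevel=2)
    X = ds.X
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - X.mean(axis=0)) / sd
    split = kennard_stone(X, n_cal)
    return ds.subset(split.calibration_indices), ds.subset(split.prediction_indices), split
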