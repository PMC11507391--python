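"""Kennard-Stone calibration/prediction partitioning and outlier screening."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import chi2


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/prediction index sets (into the input rows)."""

    calibration_idx: np.ndarray
    prediction_idx: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration_idx, dtype=int)
        pred = np.asarray(self.prediction_idx, dtype=int)
        object.__setattr__(self, "calibration_idx", cal)
        object.__setattr__(self, "prediction_idx", pred)
        if np.intersect1d(cal, pred).size:
            raise ValueError("calibration and prediction sets overlap")

    def to_frame(self, sample_ids=None):
        """Two-column table (sample_id, set in {cal, pred})."""
        import pandas as pd

        n = self.calibration_idx.size + self.prediction_idx.size
        ids = list(range(n)) if sample_ids is None else list(sample_ids)
        labels = np.empty(n, dtype=object)
        labels[self.calibration_idx] = "cal"
        labels[self.prediction_idx] = "pred"
        return pd.DataFrame({"sample_id": ids, "set": labels})


def kennard_stone(X: np.ndarray, n_cal: int) -> SplitResult:
    """Kennard-Stone maximin selection of ``n_cal`` calibration samples.

    Seeds with the globally most distant pair (Euclidean), then greedily
    adds the sample whose minimum distance to the already-selected set is
    largest; ties break to the lowest row index.  The remainder forms the
    prediction set.  Deterministic given X and n_cal.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= n_cal < n:
        raise ValueError(f"n_cal must satisfy 2 <= n_cal < {n}, got {n_cal}")
    D = cdist(X, X)
    # most distant pair; lowest (i, j) on ties
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_dist))  # argmax takes the first (lowest index) on ties
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[nxt] = -np.inf
    cal = np.sort(np.array(selected))
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(calibration_idx=cal, prediction_idx=pred, ratio=n_cal / n)


def ks_split(X: np.ndarray, ratio: float = 0.6) -> SplitResult:
    """Kennard-Stone split with |calibration| = ceil(ratio * n).

    The default 0.6 reproduces the conventional 3:2 calibration:prediction
    division (for 153 samples: 92 / 61).
    """
    n = np.asarray(X).shape[0]
    return kennard_stone(X, math.ceil(ratio * n))


def remove_outliers(
    X: np.ndarray,
    y: np.ndarray | None = None,
    alpha: float = 0.01,
    var_explained: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag spectral outliers by Mahalanobis distance in PCA score space.

    Scores are taken over the first k principal components covering
    ``var_explained`` of the variance; a sample is flagged when its squared
    Mahalanobis distance exceeds the chi-square(1 - alpha, k) quantile.
    Returns (retained_idx, flagged_idx).  ``y`` is accepted for signature
    symmetry with the modeling steps but the screen is purely spectral.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    # SVD-based PCA; eigenvalues of the covariance are s^2 / (n - 1)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2 / (n - 1)
    if ev[0] <= 0:
        raise ValueError("degenerate covariance: no spectral variance")
    frac = np.cumsum(ev) / ev.sum()
    k = int(np.searchsorted(frac, var_explained) + 1)
    k = min(k, n - 2)
    if n <= k:
        raise ValueError("too few samples for the score-space dimension")
    scores = Xc @ Vt[:k].T
    d2 = np.sum(scores**2 / ev[:k], axis=1)
    thresh = chi2.ppf(1.0 - alpha, df=k)
    flagged = np.nonzero(d2 > thresh)[0]
    retained = np.setdiff1d(np.arange(n), flagged)
    return retained, flagged
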