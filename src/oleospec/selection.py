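"""Characteristic-wavelength selection: SPA and CARS.

SPA (successive projections algorithm) is deterministic forward selection:
starting from each candidate column, it repeatedly appends the column with
the largest norm after projection onto the orthogonal complement of the
chain built so far, which minimises collinearity among the chosen
wavelengths; chains are then scored by the RMSE of a multiple linear
regression on a held-out validation split.

CARS (competitive adaptive reweighted sampling) is Monte-Carlo: each run
fits a PLS model on a random subset of calibration samples, ranks variables
by |regression coefficient|, enforces an exponentially decreasing retention
ratio (EDF), applies weighted random (adaptive reweighted) sampling, and
records the cross-validated RMSE of the surviving variable set; the set
with the lowest RMSECV wins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .partition import kennard_stone
from .regression import _center_scale, _nipals_path, cv_rmse_path


@dataclass(frozen=True)
class WavelengthSubset:
    """A selected subset of the wavelength grid plus selection diagnostics."""

    indices: np.ndarray
    wavelengths: np.ndarray
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "wavelengths", wl)
        if idx.size == 0:
            raise ValueError("empty wavelength subset")
        if np.unique(idx).size != idx.size:
            raise ValueError("duplicate indices in subset")
        if not np.all(np.diff(idx) > 0):
            raise ValueError("indices must be sorted ascending")
        if idx.size != wl.size:
            raise ValueError("indices and wavelengths length mismatch")

    def __len__(self) -> int:
        return int(self.indices.size)

    def proportion_of_full(self, n_total: int = 512) -> float:
        """Share of the full grid, in percent, rounded to 2 decimals."""
        return round(len(self) / n_total * 100.0, 2)

    def to_frame(self):
        """Delimited-table export: (index, wavelength_nm)."""
        import pandas as pd

        return pd.DataFrame({"index": self.indices, "wavelength_nm": self.wavelengths})


def edf_ratio(i: int, N: int, p: int) -> float:
    """Exponentially decreasing retention ratio r_i = a * exp(-k * i).

    The constants solve the boundary conditions r_1 = 1 (all p variables
    retained at the first run) and r_N = 2/p (two variables at the last).
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 1 <= i <= N:
        raise ValueError("run index i must lie in [1, N]")
    if N == 1:
        return 1.0
    k = math.log(p / 2.0) / (N - 1)
    return math.exp(-k * (i - 1))


def _spa_chains(Xp: np.ndarray, k_max: int) -> np.ndarray:
    """All projection chains: chains[start, j] = j-th column chosen from ``start``.

    Xp is the (centered) training matrix; each chain step deflates the
    residual matrix by the last chosen column's direction and picks the
    column of largest residual norm.  Exhausted chains (residual norms at
    numerical zero) are truncated with a warning and padded with -1.
    """
    n, p = Xp.shape
    chains = -np.ones((p, k_max), dtype=int)
    norms0 = np.einsum("ij,ij->j", Xp, Xp)
    tol = 1e-12 * max(norms0.max(), 1.0)
    truncated = False
    for start in range(p):
        R = Xp.copy()
        norms = norms0.copy()
        chain = [start]
        for step in range(1, k_max):
            last = chain[-1]
            v = R[:, last]
            nv = np.linalg.norm(v)
            if nv**2 <= tol:
                truncated = True
                break
            v = v / nv
            proj = v @ R
            R = R - np.outer(v, proj)
            norms = np.maximum(norms - proj**2, 0.0)
            norms[chain] = -1.0
            nxt = int(np.argmax(norms))
            if norms[nxt] <= tol:
                truncated = True
                break
            chain.append(nxt)
        chains[start, : len(chain)] = chain
    if truncated:
        warnings.warn("SPA chain(s) truncated at rank deficiency", stacklevel=3)
    return chains


def _mlr_rmse(Xtr, ytr, Xval, yval) -> float:
    A = np.column_stack([np.ones(Xtr.shape[0]), Xtr])
    coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
    pred = np.column_stack([np.ones(Xval.shape[0]), Xval]) @ coef
    return float(np.sqrt(np.mean((pred - yval) ** 2)))


def spa_select(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    k_max: int = 15,
    val_fraction: float = 0.3,
    wavelength_grid: np.ndarray | None = None,
) -> WavelengthSubset:
    """SPA wavelength selection on calibration data.

    Chains are built on an inner Kennard-Stone 70/30 split of the
    calibration set (so the outer prediction set is never touched) and each
    (start, length) chain is scored by MLR RMSE on the inner validation
    part; the chain with the smallest validation RMSE wins.
    """
    Xcal = np.asarray(Xcal, dtype=float)
    ycal = np.asarray(ycal, dtype=float).ravel()
    n, p = Xcal.shape
    if not 1 <= k_max <= min(n - 1, p):
        raise ValueError("k_max must be <= min(n_cal - 1, n_wavelengths)")
    split = kennard_stone(Xcal, max(2, math.ceil((1 - val_fraction) * n)))
    tr, va = split.calibration_idx, split.prediction_idx
    Xtr = Xcal[tr] - Xcal[tr].mean(axis=0)
    chains = _spa_chains(Xtr, k_max)

    rmse = np.full((p, k_max), np.inf)
    for start in range(p):
        for k in range(1, k_max + 1):
            cols = chains[start, :k]
            if cols[-1] < 0:
                break
            rmse[start, k - 1] = _mlr_rmse(
                Xcal[tr][:, cols], ycal[tr], Xcal[va][:, cols], ycal[va]
            )
    best_per_k = rmse.min(axis=0)
    k_final = int(np.argmin(best_per_k)) + 1
    start_final = int(np.argmin(rmse[:, k_final - 1]))
    cols = np.sort(chains[start_final, :k_final])
    wl = cols.astype(float) if wavelength_grid is None else np.asarray(wavelength_grid, float)[cols]
    return WavelengthSubset(
        indices=cols,
        wavelengths=wl,
        method="SPA",
        diagnostics={"rmse_by_k": best_per_k, "k": k_final, "start": start_final},
    )


def cars_select(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    n_runs: int = 50,
    seed: int = 0,
    n_components: int = 10,
    folds: int = 5,
    mc_fraction: float = 0.8,
    wavelength_grid: np.ndarray | None = None,
) -> WavelengthSubset:
    """CARS wavelength selection on calibration data.

    Per run i (i = 1..n_runs): fit PLS on a random ``mc_fraction`` of the
    calibration samples restricted to the surviving variables; rank
    variables by |coefficient|; keep the top ``edf_ratio(i) * p`` of the
    original count (forced removal), then resample that many draws with
    |coefficient|-proportional weights (adaptive reweighted sampling), the
    unique draws surviving; record the 5-fold RMSECV of the survivors.  The
    surviving set with the lowest RMSECV over all runs is returned.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    Xcal = np.asarray(Xcal, dtype=float)
    ycal = np.asarray(ycal, dtype=float).ravel()
    n, p = Xcal.shape
    rng = np.random.default_rng(seed)
    surviving = np.arange(p)
    rmsecv_trace: list[float] = []
    count_trace: list[int] = []
    sets: list[np.ndarray] = []
    n_mc = max(2, int(round(mc_fraction * n)))
    for i in range(1, n_runs + 1):
        if surviving.size < 2:
            break
        sub = rng.choice(n, size=n_mc, replace=False)
        Xs = Xcal[np.ix_(sub, surviving)]
        ys = ycal[sub]
        f = min(n_components, surviving.size, n_mc - 1)
        Xc, yc, *_ = _center_scale(Xs, ys, scale=False)
        *_, coef_path = _nipals_path(Xc, yc, f)
        if coef_path.shape[1] == 0:  # no usable component on this subsample
            break
        w = np.abs(coef_path[:, -1])
        keep = max(2, int(round(edf_ratio(i, n_runs, p) * p)))
        if keep < surviving.size:
            order = np.argsort(-w)
            surviving = np.sort(surviving[order[:keep]])
            w = w[order[:keep]]
        if w.sum() <= 0:
            break
        draws = rng.choice(surviving.size, size=surviving.size, replace=True, p=w / w.sum())
        surviving = np.sort(surviving[np.unique(draws)])
        if surviving.size < 2:
            break
        f_cv = min(n_components, surviving.size)
        rmse = cv_rmse_path(
            Xcal[:, surviving], ycal, f_cv, folds=folds,
            seed=int(rng.integers(2**31)),
        )
        rmsecv_trace.append(float(rmse.min()))
        count_trace.append(int(surviving.size))
        sets.append(surviving.copy())
    if not sets:
        raise RuntimeError("CARS retained no variable sets")
    best = int(np.argmin(rmsecv_trace))
    idx = sets[best]
    wl = idx.astype(float) if wavelength_grid is None else np.asarray(wavelength_grid, float)[idx]
    return WavelengthSubset(
        indices=idx,
        wavelengths=wl,
        method="CARS",
        diagnostics={
            "rmsecv": np.array(rmsecv_trace),
            "n_variables": np.array(count_trace),
            "best_run": best + 1,
        },
    )


def attach_wavelengths(subset: WavelengthSubset, grid: np.ndarray) -> WavelengthSubset:
    """Return the subset with physical wavelengths (nm) looked up on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    return WavelengthSubset(
        indices=subset.indices,
        wavelengths=grid[subset.indices],
        method=subset.method,
        diagnostics=subset.diagnostics,
    )
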