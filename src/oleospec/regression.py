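"""Latent-variable calibration models: PCR and PLSR (NIPALS, univariate y).

Both models mean-center X and y; optional column autoscaling (unit
variance) is used for fused spectral+texture feature blocks where columns
differ by orders of magnitude.  PCR decomposes the centered spectral matrix
A = F P' + E by SVD, keeps the f leading score vectors F and regresses y on
them; PLSR builds components that maximise covariance with y (NIPALS) and
regresses y on those scores, which handles the strong collinearity of
neighbouring NIR bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_RANK_TOL = 1e-10


@dataclass
class PcrModel:
    """Principal component regression: y ~ scores of the leading f PCs."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    loadings: np.ndarray  # (p, f), orthonormal columns
    coef_scores: np.ndarray  # (f,), regression weights on scores
    y_mean: float
    n_components: int

    @property
    def coef(self) -> np.ndarray:
        """Coefficients on the (centered, scaled) original variables."""
        return self.loadings @ self.coef_scores


@dataclass
class PlsModel:
    """PLS1 regression model (NIPALS factorisation)."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray  # W (p, f)
    x_loadings: np.ndarray  # P (p, f)
    y_loadings: np.ndarray  # q (f,)
    scores: np.ndarray  # T (n, f), training scores
    coef: np.ndarray  # (p,), on centered/scaled variables
    n_components: int


def _center_scale(X, y, scale):
    """Center X and y; ``scale`` may be False, True (unit column variance),
    or an array of per-column factors applied on top of autoscaling (used
    for block scaling of fused feature matrices)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    x_mean = X.mean(axis=0)
    if scale is False or scale is None:
        x_scale = np.ones(X.shape[1])
    else:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
        if not isinstance(scale, bool):
            factors = np.asarray(scale, dtype=float)
            if factors.shape != (X.shape[1],):
                raise ValueError("per-column scale factors must match column count")
            x_scale = x_scale * factors
    Xc = (X - x_mean) / x_scale
    y_mean = float(y.mean())
    return Xc, y - y_mean, x_mean, x_scale, y_mean


def fit_pcr(X: np.ndarray, y: np.ndarray, n_components: int, scale: bool = False) -> PcrModel:
    """Fit PCR with ``n_components`` principal components.

    Raises if ``n_components`` exceeds the rank of the centered matrix.
    """
    Xc, yc, x_mean, x_scale, y_mean = _center_scale(X, y, scale)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * s[0])) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds rank {rank}")
    scores = U[:, :n_components] * s[:n_components]
    coef_scores, *_ = np.linalg.lstsq(scores, yc, rcond=None)
    return PcrModel(
        x_mean=x_mean,
        x_scale=x_scale,
        loadings=Vt[:n_components].T,
        coef_scores=coef_scores,
        y_mean=y_mean,
        n_components=n_components,
    )


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, f_max: int):
    """NIPALS PLS1 factors and the coefficient vector after each component.

    Returns (W, P, q, T, coef_path) where coef_path[:, a] are the
    coefficients of the (a+1)-component model — nested models come free,
    which the cross-validation and CARS loops exploit.
    """
    n, p = Xc.shape
    f_max = min(f_max, n - 1, p)
    W = np.zeros((p, f_max))
    P = np.zeros((p, f_max))
    q = np.zeros(f_max)
    T = np.zeros((n, f_max))
    Xd, yd = Xc.copy(), yc.copy()
    n_comp = 0
    for a in range(f_max):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= _RANK_TOL:
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt <= _RANK_TOL:
            break
        pvec = (Xd.T @ t) / tt
        qa = (yd @ t) / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
        Xd -= np.outer(t, pvec)
        yd -= qa * t
        n_comp = a + 1
    W, P, q, T = W[:, :n_comp], P[:, :n_comp], q[:n_comp], T[:, :n_comp]
    coef_path = np.zeros((p, n_comp))
    # B_f = W_f (P_f' W_f)^{-1} q_f
    for f in range(1, n_comp + 1):
        coef_path[:, f - 1] = W[:, :f] @ np.linalg.solve(P[:, :f].T @ W[:, :f], q[:f])
    return W, P, q, T, coef_path


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int, scale: bool = False) -> PlsModel:
    """Fit a PLS1 model by NIPALS with ``n_components`` latent variables."""
    Xc, yc, x_mean, x_scale, y_mean = _center_scale(X, y, scale)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if np.allclose(yc, 0):
        raise ValueError("y has zero variance")
    W, P, q, T, coef_path = _nipals_path(Xc, yc, n_components)
    if W.shape[1] < n_components:
        raise ValueError(
            f"requested {n_components} components but X supports only {W.shape[1]}"
        )
    return PlsModel(
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef=coef_path[:, n_components - 1],
        n_components=n_components,
    )


def predict(model: PcrModel | PlsModel, X: np.ndarray) -> np.ndarray:
    """Apply a fitted model to new spectra (columns must match training)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"expected {model.x_mean.size} columns, got {X.shape[1]}"
        )
    Xc = (X - model.x_mean) / model.x_scale
    return Xc @ model.coef + model.y_mean


def save_model(model: PcrModel | PlsModel, path: str) -> None:
    """Serialize a fitted model to JSON (coefficients, centering, metadata)."""
    import json

    kind = "pcr" if isinstance(model, PcrModel) else "plsr"
    payload = {"kind": kind, "n_components": model.n_components}
    for key, val in vars(model).items():
        if isinstance(val, np.ndarray):
            payload[key] = val.tolist()
        else:
            payload[key] = val
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str) -> PcrModel | PlsModel:
    """Reload a model written by :func:`save_model`; predict-compatible."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    kind = payload.pop("kind")
    cls = PcrModel if kind == "pcr" else PlsModel
    fields = {
        k: (np.asarray(v) if isinstance(v, list) else v) for k, v in payload.items()
    }
    return cls(**fields)


def _cv_folds(n: int, folds: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    return np.array_split(idx, folds)


def cv_rmse_path(
    X: np.ndarray,
    y: np.ndarray,
    f_max: int,
    folds: int = 5,
    seed: int = 0,
    scale: bool = False,
    model: str = "plsr",
) -> np.ndarray:
    """k-fold cross-validated RMSE for 1..f_max components (one fit per fold)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    rng = np.random.default_rng(seed)
    f_cap = min(f_max, X.shape[1], n - max(2, n // folds) - 1)
    f_cap = max(f_cap, 1)
    sq_err = np.zeros(f_cap)
    counts = np.zeros(f_cap)
    for test_idx in _cv_folds(n, folds, rng):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xtr, ytr = X[train_idx], y[train_idx]
        Xte, yte = X[test_idx], y[test_idx]
        Xc, yc, x_mean, x_scale, y_mean = _center_scale(Xtr, ytr, scale)
        if model == "plsr":
            *_, coef_path = _nipals_path(Xc, yc, f_cap)
        elif model == "pcr":
            U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
            rank = int(np.sum(s > _RANK_TOL * s[0]))
            a = min(f_cap, rank)
            coef_path = np.zeros((X.shape[1], a))
            uy = U.T @ yc
            for f in range(1, a + 1):
                coef_path[:, f - 1] = Vt[:f].T @ (uy[:f] / s[:f])
        else:
            raise ValueError("model must be 'plsr' or 'pcr'")
        a = coef_path.shape[1]
        if a == 0:  # degenerate fold: intercept-only predictions
            sq_err += ((y_mean - yte) ** 2).sum()
        else:
            pred = ((Xte - x_mean) / x_scale) @ coef_path + y_mean
            err2 = (pred - yte[:, None]) ** 2
            sq_err[:a] += err2.sum(axis=0)
            if a < f_cap:  # pad with the deepest available model
                sq_err[a:] += err2[:, -1].sum()
        counts[:] += yte.size
    return np.sqrt(sq_err / counts)


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    f_max: int = 12,
    folds: int = 5,
    seed: int = 0,
    scale: bool = False,
    model: str = "plsr",
) -> int:
    """Choose the component count by k-fold CV RMSE with a one-SE rule.

    The smallest f whose CV RMSE is within one standard error of the
    minimum is returned, trading a little apparent fit for stability.
    """
    rmse = cv_rmse_path(X, y, f_max, folds=folds, seed=seed, scale=scale, model=model)
    best = int(np.argmin(rmse))
    n = np.asarray(y).size
    se = rmse[best] / np.sqrt(2.0 * n)
    ok = np.nonzero(rmse <= rmse[best] + se)[0]
    return int(ok[0]) + 1
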