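"""Metrics, feature fusion, model comparison and the three-tier experiment.

The experiment mirrors the standard escalation in hyperspectral calibration
studies: (a) PCR and PLSR on all 512 wavelengths under each pretreatment;
(b) the same models on SPA- and CARS-selected characteristic wavelengths;
(c) models on characteristic-wavelength spectra fused with GLCM texture
features extracted from the images at those wavelengths.  Models are
labelled the conventional way, e.g. "2Der-SPA-GLCM-PLSR".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SpectrumSet
from .envi import segment_roi
from .partition import ks_split, SplitResult
from .preprocess import STANDARD_METHODS, apply_pretreatments
from .regression import fit_pcr, fit_plsr, predict, select_components
from .selection import WavelengthSubset, attach_wavelengths, cars_select, spa_select
from .synthetic import Cohort, SpectralSceneSpec, generate_cohort
from .texture import GlcmSpec, texture_vector


@dataclass(frozen=True)
class EvaluationMetrics:
    """Rc2/RMSEC on the calibration set, Rp2/RMSEP on the prediction set."""

    rc2: float
    rmsec: float
    rp2: float
    rmsep: float


def metrics(y_true, y_pred, mode: str = "pearson") -> tuple[float, float]:
    """(R^2, RMSE) of predictions against reference values.

    R^2 is the squared Pearson correlation by default — the convention in
    the NIR calibration literature, where R refers to the correlation
    between measured and predicted values; ``mode="cod"`` gives the
    coefficient of determination instead.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    if y_true.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(y_true) == 0:
        raise ValueError("reference values have zero spread")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.std(y_pred) == 0:
        warnings.warn("constant predictions: R^2 reported as 0", stacklevel=2)
        return 0.0, rmse
    if mode == "pearson":
        r2 = float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    elif mode == "cod":
        ss_res = np.sum((y_true - y_pred) ** 2)
        ss_tot = np.sum((y_true - y_true.mean()) ** 2)
        r2 = float(1.0 - ss_res / ss_tot)
    else:
        raise ValueError("mode must be 'pearson' or 'cod'")
    return r2, rmse


def fuse_features(spectral_block: np.ndarray, texture_block: np.ndarray | None) -> np.ndarray:
    """Column-wise concatenation, spectral block first."""
    spectral_block = np.asarray(spectral_block, dtype=float)
    if texture_block is None or np.asarray(texture_block).size == 0:
        return spectral_block
    texture_block = np.asarray(texture_block, dtype=float)
    if spectral_block.shape[0] != texture_block.shape[0]:
        raise ValueError("row counts differ between spectral and texture blocks")
    return np.hstack([spectral_block, texture_block])


def improvement(old: float, new: float, convention: str = "relative") -> float:
    """Percentage improvement between two metric values, 2-decimal rounded.

    ``relative``: (new - old) / old * 100.  ``absolute_pp``: (new - old) * 100,
    i.e. percentage points.  Both conventions are common in the applied
    literature, sometimes within one report, so both are first-class here.
    """
    if not (0 <= old <= 1 and 0 <= new <= 1):
        raise ValueError("metric values must lie in [0, 1]")
    if convention == "relative":
        if old == 0:
            raise ValueError("relative improvement undefined for old == 0")
        return round((new - old) / old * 100.0, 2)
    if convention == "absolute_pp":
        return round((new - old) * 100.0, 2)
    raise ValueError("convention must be 'relative' or 'absolute_pp'")


@dataclass
class ModelResult:
    """One fitted calibration model with its evaluation."""

    label: str
    model_type: str  # "PCR" | "PLSR"
    n_components: int
    n_features: int
    metrics: EvaluationMetrics
    y_cal: np.ndarray
    yhat_cal: np.ndarray
    y_pred: np.ndarray
    yhat_pred: np.ndarray


@dataclass
class ComparisonReport:
    """All fitted models of one experiment plus provenance."""

    results: dict[str, ModelResult]
    split: SplitResult
    subsets: dict[str, WavelengthSubset]
    config: "ExperimentConfig"

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "label": r.label,
                "model": r.model_type,
                "n_features": r.n_features,
                "n_components": r.n_components,
                "Rc2": round(r.metrics.rc2, 4),
                "RMSEC": round(r.metrics.rmsec, 4),
                "Rp2": round(r.metrics.rp2, 4),
                "RMSEP": round(r.metrics.rmsep, 4),
            }
            for r in self.results.values()
        ]
        return pd.DataFrame(rows)

    def improvement(
        self, old_label: str, new_label: str, metric: str = "rp2",
        convention: str = "relative",
    ) -> float:
        old = getattr(self.results[old_label].metrics, metric)
        new = getattr(self.results[new_label].metrics, metric)
        return improvement(old, new, convention)

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str) -> None:
        self.table.to_json(path, orient="records", indent=2)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun one three-tier experiment."""

    n_samples: int = 153
    seed: int = 42
    texture_coupling: float = 0.6
    cal_ratio: float = 0.6
    preprocess_methods: tuple[str, ...] = tuple(STANDARD_METHODS)
    selection_preprocessing: str = "2Der"
    spa_k_max: int = 12
    cars_runs: int = 50
    f_max: int = 12
    cv_folds: int = 5
    glcm: GlcmSpec = field(default_factory=GlcmSpec)
    autoscale_fused: bool = True
    block_scale_fused: bool = True
    r2_mode: str = "pearson"
    cube_shape: tuple[int, int] = (80, 80)
    scene: SpectralSceneSpec | None = None

    def scene_spec(self) -> SpectralSceneSpec:
        if self.scene is not None:
            return self.scene
        return SpectralSceneSpec(texture_coupling=self.texture_coupling)


def _fit_and_eval(
    label: str,
    model_type: str,
    Xcal: np.ndarray,
    ycal: np.ndarray,
    Xpred: np.ndarray,
    ypred: np.ndarray,
    cfg: ExperimentConfig,
    scale: bool,
) -> ModelResult:
    kind = "pcr" if model_type == "PCR" else "plsr"
    f = select_components(
        Xcal, ycal, f_max=cfg.f_max, folds=cfg.cv_folds, seed=cfg.seed,
        scale=scale, model=kind,
    )
    fit = fit_pcr if kind == "pcr" else fit_plsr
    model = fit(Xcal, ycal, f, scale=scale)
    yhat_c = predict(model, Xcal)
    yhat_p = predict(model, Xpred)
    rc2, rmsec = metrics(ycal, yhat_c, mode=cfg.r2_mode)
    rp2, rmsep = metrics(ypred, yhat_p, mode=cfg.r2_mode)
    return ModelResult(
        label=label,
        model_type=model_type,
        n_components=f,
        n_features=Xcal.shape[1],
        metrics=EvaluationMetrics(rc2=rc2, rmsec=rmsec, rp2=rp2, rmsep=rmsep),
        y_cal=ycal,
        yhat_cal=yhat_c,
        y_pred=ypred,
        yhat_pred=yhat_p,
    )


def _texture_block(cohort: Cohort, subset: WavelengthSubset, cfg: ExperimentConfig) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    rows = []
    for i in range(len(cohort.cubes)):
        cube, _ = cohort.cubes.subcube(i, subset.indices)
        roi = segment_roi(cube)
        # erode so segmentation slop at the dish rim cannot leak background
        # pixels into the gray-level range
        core = binary_erosion(roi.mask, iterations=3)
        m = core if core.any() else roi.mask
        rows.append(texture_vector(cube, m, range(len(subset)), cfg.glcm))
    return np.vstack(rows)


def run_experiment(cfg: ExperimentConfig, cohort: Cohort | None = None) -> ComparisonReport:
    """Run the full three-tier comparison on a (default: synthetic) cohort.

    Stage failures are re-raised with the pipeline stage named.  The
    Kennard-Stone split is computed once — on the spectra preprocessed with
    ``selection_preprocessing``, the representation the headline models use
    — and shared by every model so all tiers compare on common sample sets.
    """
    if cohort is None:
        cohort = generate_cohort(
            n=cfg.n_samples, spec=cfg.scene_spec(), seed=cfg.seed,
            cube_shape=cfg.cube_shape,
        )
    y = cohort.av
    pre: dict[str, SpectrumSet] = {}
    for name in cfg.preprocess_methods:
        try:
            pre[name] = apply_pretreatments(cohort.spectra, name)
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"preprocessing stage {name!r} failed") from exc

    sel_name = cfg.selection_preprocessing
    if sel_name not in pre:
        pre[sel_name] = apply_pretreatments(cohort.spectra, sel_name)
    split = ks_split(pre[sel_name].X, ratio=cfg.cal_ratio)
    cal, prd = split.calibration_idx, split.prediction_idx

    results: dict[str, ModelResult] = {}
    # tier (a): full wavelengths, every pretreatment, PCR and PLSR
    for name, sset in pre.items():
        for model_type in ("PCR", "PLSR"):
            label = f"{name}-{model_type}"
            try:
                results[label] = _fit_and_eval(
                    label, model_type, sset.X[cal], y[cal], sset.X[prd], y[prd],
                    cfg, scale=False,
                )
            except Exception as exc:
                raise RuntimeError(f"full-wavelength modeling stage {label!r} failed") from exc

    # tier (b): characteristic wavelengths on the selection representation
    Xsel = pre[sel_name].X
    grid = pre[sel_name].wavelengths
    try:
        spa = spa_select(Xsel[cal], y[cal], k_max=cfg.spa_k_max, wavelength_grid=grid)
    except Exception as exc:
        raise RuntimeError("SPA selection stage failed") from exc
    try:
        cars = cars_select(
            Xsel[cal], y[cal], n_runs=cfg.cars_runs, seed=cfg.seed,
            folds=cfg.cv_folds, wavelength_grid=grid,
        )
    except Exception as exc:
        raise RuntimeError("CARS selection stage failed") from exc
    subsets = {"SPA": spa, "CARS": cars}
    for sname, subset in subsets.items():
        for model_type in ("PCR", "PLSR"):
            label = f"{sel_name}-{sname}-{model_type}"
            results[label] = _fit_and_eval(
                label, model_type,
                Xsel[np.ix_(cal, subset.indices)], y[cal],
                Xsel[np.ix_(prd, subset.indices)], y[prd],
                cfg, scale=False,
            )

    # tier (c): SPA spectral block fused with GLCM texture features
    try:
        tex = _texture_block(cohort, spa, cfg)
    except Exception as exc:
        raise RuntimeError("texture extraction stage failed") from exc
    fused = fuse_features(Xsel[:, spa.indices], tex)
    if cfg.autoscale_fused and cfg.block_scale_fused:
        # block scaling: after autoscaling, weight each block by 1/sqrt(width)
        # so the handful of spectral columns and the texture block contribute
        # equal total variance
        n_s, n_t = len(spa), tex.shape[1]
        fused_scale = np.concatenate(
            [np.full(n_s, np.sqrt(n_s)), np.full(n_t, np.sqrt(n_t))]
        )
    else:
        fused_scale = cfg.autoscale_fused
    for model_type in ("PCR", "PLSR"):
        label = f"{sel_name}-SPA-GLCM-{model_type}"
        results[label] = _fit_and_eval(
            label, model_type, fused[cal], y[cal], fused[prd], y[prd],
            cfg, scale=fused_scale,
        )

    return ComparisonReport(results=results, split=split, subsets=subsets, config=cfg)
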