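"""Spectral pretreatments: SG smoothing/derivatives, SNV, min-max, baseline.

Every operation is per-spectrum (fit-free: nothing is learned from the
calibration set), preserves the (n_samples, n_wavelengths) shape and sample
order, and appends its tag to the set's provenance.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .containers import SpectrumSet

_DERIV_TAGS = {0: "SG", 1: "1Der", 2: "2Der"}


def savgol(s: SpectrumSet, window: int = 11, polyorder: int = 2, deriv: int = 0) -> SpectrumSet:
    """Savitzky-Golay filtering; ``deriv`` 0/1/2 gives SG / 1Der / 2Der.

    Derivatives are scaled by the band spacing (units per nm).  Edges are
    handled by polynomial extrapolation so the wavelength axis keeps its
    full length.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if deriv not in _DERIV_TAGS:
        raise ValueError("deriv must be 0, 1 or 2")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    if window > s.n_wavelengths:
        raise ValueError("window exceeds number of wavelengths")
    delta = float(np.mean(np.diff(s.wavelengths)))
    X = savgol_filter(
        s.X, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=delta, axis=1, mode="interp",
    )
    return s.with_data(X, _DERIV_TAGS[deriv])


def snv(s: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: per-spectrum center and scale to unit sd (ddof=1)."""
    mean = s.X.mean(axis=1, keepdims=True)
    sd = s.X.std(axis=1, ddof=1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        raise ValueError(f"constant spectrum: sample {s.sample_ids[flat[0]]!r}")
    return s.with_data((s.X - mean) / sd, "SNV")


def minmax_normalize(s: SpectrumSet) -> SpectrumSet:
    """Map each spectrum onto [0, 1] by its own min and max."""
    lo = s.X.min(axis=1, keepdims=True)
    hi = s.X.max(axis=1, keepdims=True)
    flat = np.nonzero((hi - lo).ravel() == 0)[0]
    if flat.size:
        raise ValueError(f"constant spectrum: sample {s.sample_ids[flat[0]]!r}")
    return s.with_data((s.X - lo) / (hi - lo), "Normalize")


def baseline_correct(s: SpectrumSet) -> SpectrumSet:
    """Remove each spectrum's least-squares straight line in wavelength."""
    if s.n_wavelengths < 3:
        raise ValueError("need at least 3 bands for a linear baseline")
    wl = s.wavelengths
    A = np.column_stack([np.ones_like(wl), wl - wl.mean()])
    coef, *_ = np.linalg.lstsq(A, s.X.T, rcond=None)
    return s.with_data(s.X - (A @ coef).T, "Baseline")


#: Registry for config-driven pipelines: name -> callable(set, **kwargs).
PRETREATMENTS = {
    "savgol": savgol,
    "snv": snv,
    "normalize": minmax_normalize,
    "baseline": baseline_correct,
}

#: The study's pretreatment menu, by label, as keyword recipes.
STANDARD_METHODS: dict[str, list[dict]] = {
    "Raw": [],
    "Normalize": [{"method": "normalize"}],
    "1Der": [{"method": "savgol", "window": 11, "polyorder": 2, "deriv": 1}],
    "2Der": [{"method": "savgol", "window": 11, "polyorder": 2, "deriv": 2}],
    "Baseline": [{"method": "baseline"}],
    "SNV": [{"method": "snv"}],
    "SG": [{"method": "savgol", "window": 11, "polyorder": 2, "deriv": 0}],
}


def apply_pretreatments(s: SpectrumSet, recipe) -> SpectrumSet:
    """Apply a recipe: either a label from STANDARD_METHODS or a list of
    ``{"method": name, **kwargs}`` steps, in order."""
    if isinstance(recipe, str):
        recipe = STANDARD_METHODS[recipe]
    out = s
    for step in recipe:
        step = dict(step)
        fn = PRETREATMENTS[step.pop("method")]
        out = fn(out, **step)
    return out
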