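"""Gray-level co-occurrence matrix (GLCM) texture features.

The GLCM p(i, j | d, theta) is the joint probability that a pixel of gray
level i has a neighbour of gray level j at offset distance d in direction
theta.  Four Haralick-style statistics summarise it:

    f1  inverse difference moment   sum p(i,j) / (1 + (i-j)^2)
    f2  angular second moment       sum p(i,j)^2
    f3  entropy                     -sum p(i,j) log p(i,j)   (natural log)
    f4  correlation                 (sum ij p(i,j) - u1 u2) / sqrt(s1^2 s2^2)

computed at the four standard directions 0, 45, 90, 135 degrees.  The
implementation is mask-aware: both pixels of a pair must lie inside the ROI
so the dark background never contaminates the oil texture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: (row, col) offsets for the four directions, image rows increasing downward.
DIRECTION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
DIRECTIONS = (0, 45, 90, 135)
FEATURE_NAMES = ("f1", "f2", "f3", "f4")


@dataclass(frozen=True)
class GlcmSpec:
    """Offset distance d (pixels), gray-level count, symmetry flag."""

    d: int = 1
    levels: int = 64
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("offset distance d must be >= 1")
        if self.levels < 2:
            raise ValueError("need at least 2 gray levels")


def quantize(image: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Linear binning of masked-pixel intensities into ``levels`` gray levels.

    The bin edges span the masked min..max range; background pixels get
    level 0 but are excluded from co-occurrence counting by the mask.
    Affine (positive-gain) intensity transforms leave the output unchanged.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        warnings.warn("zero intensity range: all pixels map to level 0", stacklevel=2)
        return np.zeros(image.shape, dtype=np.int32)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


def glcm(raster: np.ndarray, mask: np.ndarray, spec: GlcmSpec, theta: int) -> np.ndarray:
    """Normalised (and, by default, symmetrised) GLCM for one direction.

    Counts (i, j) gray-level pairs at the offset for ``theta``; only pairs
    with both pixels inside the mask contribute.
    """
    raster = np.asarray(raster)
    mask = np.asarray(mask, dtype=bool)
    if raster.shape != mask.shape:
        raise ValueError("raster and mask shapes differ")
    if theta not in DIRECTION_OFFSETS:
        raise ValueError(f"theta must be one of {DIRECTIONS}")
    dr, dc = DIRECTION_OFFSETS[theta]
    dr, dc = dr * spec.d, dc * spec.d
    rows, cols = raster.shape
    r0 = max(0, -dr)
    r1 = min(rows, rows - dr)
    c0 = max(0, -dc)
    c1 = min(cols, cols - dc)
    src = (slice(r0, r1), slice(c0, c1))
    dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
    valid = mask[src] & mask[dst]
    i = raster[src][valid].astype(np.int64)
    j = raster[dst][valid].astype(np.int64)
    if i.size == 0:
        raise ValueError("no valid pixel pairs inside the mask at this offset")
    k = spec.levels
    counts = np.bincount(i * k + j, minlength=k * k).reshape(k, k).astype(float)
    if spec.symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def glcm_features(p: np.ndarray) -> tuple[float, float, float, float]:
    """(f1, f2, f3, f4) of a normalised GLCM.

    Zero entries contribute nothing to the entropy; when either marginal
    variance vanishes the correlation f4 is defined as 0 so constant ROIs
    stay finite.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("GLCM must be normalised to sum 1")
    k = p.shape[0]
    i = np.arange(1, k + 1, dtype=float)  # 1-based gray-level labels
    ii, jj = np.meshgrid(i, i, indexing="ij")
    f1 = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    f2 = float(np.sum(p**2))
    nz = p > 0
    f3 = float(-np.sum(p[nz] * np.log(p[nz])))
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    u1 = float(i @ pi)
    u2 = float(i @ pj)
    s1 = float(((i - u1) ** 2) @ pi)
    s2 = float(((i - u2) ** 2) @ pj)
    if s1 * s2 <= 0:
        warnings.warn("zero marginal variance: correlation f4 set to 0", stacklevel=2)
        f4 = 0.0
    else:
        f4 = float((np.sum(ii * jj * p) - u1 * u2) / np.sqrt(s1 * s2))
    return f1, f2, f3, f4


def texture_vector(
    cube,
    mask,
    band_indices,
    spec: GlcmSpec | None = None,
) -> np.ndarray:
    """The fused-image feature row for one sample.

    For each selected wavelength image: 4 directions x (f1..f4) = 16 values;
    ordering is wavelength-major, then direction (0, 45, 90, 135), then
    f1..f4 — 64 values for the usual 4 selected wavelengths.
    """
    spec = spec or GlcmSpec()
    data = np.asarray(cube.data, dtype=float) if hasattr(cube, "data") else np.asarray(cube, dtype=float)
    m = mask.mask if hasattr(mask, "mask") else np.asarray(mask, dtype=bool)
    out = []
    for b in band_indices:
        q = quantize(data[:, :, int(b)], m, spec.levels)
        for theta in DIRECTIONS:
            out.extend(glcm_features(glcm(q, m, spec, theta)))
    return np.array(out)


def texture_feature_names(wavelengths) -> list[str]:
    """Column names matching :func:`texture_vector` ordering."""
    return [
        f"w{w:.2f}_t{theta}_{f}"
        for w in wavelengths
        for theta in DIRECTIONS
        for f in FEATURE_NAMES
    ]
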