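"""ENVI cube I/O, reflectance calibration, ROI segmentation, spectrum extraction.

The ENVI container is a plain-text ``.hdr`` describing a raw binary raster
(``.img``) in one of three interleaves: BSQ (band-sequential), BIL
(band-interleaved-by-line), BIP (band-interleaved-by-pixel).  In-memory the
cube is always row-major ``(rows, cols, bands)`` with 0-based indices.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu


class EnviFormatError(ValueError):
    """Malformed or unsupported ENVI header/raster."""


# ENVI "data type" codes for the dtypes this package writes/reads.
_DTYPE_TO_CODE = {np.dtype("float32"): 4, np.dtype("float64"): 5, np.dtype("uint16"): 12}
_CODE_TO_DTYPE = {v: k for k, v in _DTYPE_TO_CODE.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class Hypercube:
    """A reflectance (or raw-count) cube: ``data[rows, cols, bands]``."""

    data: np.ndarray
    wavelengths: np.ndarray
    interleave: str = "bsq"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"bands {self.data.shape[2]} != wavelength count {self.wavelengths.size}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube data must be finite")
        if self.interleave.lower() not in _INTERLEAVES:
            raise ValueError(f"unknown interleave {self.interleave!r}")
        self.interleave = self.interleave.lower()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class RoiMask:
    """Boolean raster marking the oil region of interest."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def count(self) -> int:
        return int(self.mask.sum())


def _axes_order(interleave: str) -> tuple[int, int, int]:
    # file-axis order, expressed as a transpose of (rows, cols, bands)
    return {"bsq": (2, 0, 1), "bil": (0, 2, 1), "bip": (0, 1, 2)}[interleave]


def write_envi(cube: Hypercube, path: str) -> tuple[str, str]:
    """Write ``<path>.hdr`` + ``<path>.img``; returns both file paths.

    Roundtrips bit-exactly through :func:`read_envi` for float32/float64/
    uint16 data in any of the three interleaves.
    """
    base, ext = os.path.splitext(path)
    if ext.lower() in (".hdr", ".img"):
        path = base
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_TO_CODE:
        raise EnviFormatError(f"unsupported dtype {dtype}")
    rows, cols, bands = cube.data.shape
    hdr_path, img_path = path + ".hdr", path + ".img"
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        "description = {oleospec hyperspectral cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_TO_CODE[dtype]}",
        f"interleave = {cube.interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {" + wl + "}",
    ]
    with open(hdr_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    np.ascontiguousarray(cube.data.transpose(_axes_order(cube.interleave))).tofile(img_path)
    return hdr_path, img_path


def _parse_header(text: str) -> dict:
    fields: dict[str, str] = {}
    body = text
    if body.lstrip().startswith("ENVI"):
        body = body.lstrip()[4:]
    i = 0
    # key = value lines; values in {...} may span lines
    while i < len(body):
        eq = body.find("=", i)
        if eq == -1:
            break
        key = body[i:eq].strip().lower()
        rest = body[eq + 1 :].lstrip()
        if rest.startswith("{"):
            close = rest.find("}")
            if close == -1:
                raise EnviFormatError("unterminated { } block in header")
            value = rest[1:close]
            consumed = (eq + 1) + (len(body[eq + 1 :]) - len(rest)) + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl == -1 else nl
            value = rest[:nl]
            consumed = (eq + 1) + (len(body[eq + 1 :]) - len(rest)) + nl
        if key:
            fields[key.strip()] = value.strip()
        i = consumed
    return fields


def read_envi(header_path: str) -> Hypercube:
    """Read an ENVI cube given the path of its ``.hdr`` file."""
    with open(header_path) as fh:
        fields = _parse_header(fh.read())
    for req in ("samples", "lines", "bands", "data type", "interleave"):
        if req not in fields:
            raise EnviFormatError(f"header missing required field {req!r}")
    if "wavelength" not in fields:
        raise EnviFormatError("header missing wavelength block")
    cols, rows, bands = (int(fields[k]) for k in ("samples", "lines", "bands"))
    code = int(fields["data type"])
    if code not in _CODE_TO_DTYPE:
        raise EnviFormatError(f"unsupported ENVI data type code {code}")
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unknown interleave {fields['interleave']!r}")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace("\n", " ").split(",") if tok.strip()]
    )
    if wavelengths.size != bands:
        raise EnviFormatError(
            f"wavelength count {wavelengths.size} != bands {bands}"
        )
    img_path = os.path.splitext(header_path)[0] + ".img"
    raw = np.fromfile(img_path, dtype=_CODE_TO_DTYPE[code])
    expected = rows * cols * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"raster holds {raw.size} values, header declares {expected}"
        )
    order = _axes_order(interleave)
    file_shape = tuple((rows, cols, bands)[a] for a in order)
    data = raw.reshape(file_shape).transpose(np.argsort(order))
    return Hypercube(data=data, wavelengths=wavelengths, interleave=interleave)


def average_replicates(spectra) -> np.ndarray:
    """Elementwise mean of replicate spectra (e.g. three repeat scans)."""
    arrs = [np.asarray(s, dtype=float) for s in spectra]
    if not arrs:
        raise ValueError("no replicates given")
    n = arrs[0].size
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("replicates differ in length")
    return np.mean(arrs, axis=0)


def average_reference_frames(frames: np.ndarray) -> np.ndarray:
    """Average a stack of white/dark reference frames (frames, rows, cols, bands)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 4:
        raise ValueError("expected a 4-D stack (frames, rows, cols, bands)")
    if frames.shape[0] < 1:
        raise ValueError("empty reference stack")
    return frames.mean(axis=0)


def calibrate_reflectance(raw: Hypercube, white, dark) -> Hypercube:
    """Per-pixel, per-band reflectance: R = (raw - dark) / (white - dark).

    ``white``/``dark`` are arrays of the same shape as the cube (already
    averaged over reference frames).  Output is clipped to [0, 1.05].
    """
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    data = np.asarray(raw.data, dtype=float)
    if white.shape != data.shape or dark.shape != data.shape:
        raise ValueError("raw, white and dark shapes must agree")
    denom = white - dark
    bad = np.nonzero(~np.all(denom > 0, axis=(0, 1)))[0]
    if bad.size:
        raise ValueError(
            f"white equals (or falls below) dark at band index {int(bad[0])}"
        )
    refl = np.clip((data - dark) / denom, 0.0, 1.05)
    return Hypercube(
        data=refl,
        wavelengths=raw.wavelengths,
        interleave=raw.interleave,
        metadata={**raw.metadata, "calibrated": True},
    )


def segment_roi(
    cube: Hypercube,
    band_window: tuple[float, float] | None = None,
    threshold: float | None = None,
) -> RoiMask:
    """Segment the oil region from the dark background.

    The mean reflectance image over ``band_window`` (a wavelength range in
    nm; full range if omitted) is thresholded — Otsu's method when no manual
    ``threshold`` is given — and the largest connected component is kept.
    """
    wl = cube.wavelengths
    if band_window is None:
        sel = slice(None)
    else:
        lo, hi = band_window
        idx = np.nonzero((wl >= lo) & (wl <= hi))[0]
        if idx.size == 0:
            raise ValueError("band_window selects no bands")
        sel = idx
    mean_img = np.asarray(cube.data, dtype=float)[:, :, sel].mean(axis=2)
    if threshold is None:
        if np.ptp(mean_img) == 0:
            raise ValueError("flat image: cannot choose a threshold")
        threshold = float(threshold_otsu(mean_img))
    mask = mean_img > threshold
    if not mask.any():
        raise ValueError("ROI segmentation produced an empty mask")
    labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return RoiMask(mask=mask)


def mean_spectrum(cube: Hypercube, mask: RoiMask | np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean over the masked pixels."""
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, dtype=bool)
    if m.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    if not m.any():
        raise ValueError("empty mask")
    return np.asarray(cube.data, dtype=float)[m].mean(axis=0)
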