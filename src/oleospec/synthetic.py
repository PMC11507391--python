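"""Synthetic camellia-oil cohorts: AV references, NIR spectra, imaging scenes.

The study system is camellia seed oil imaged in the 870-1720 nm short-wave
infrared range.  Oil spectra show strong absorption near 1115 nm (C-H
stretch), 1330 nm (C-H bend, sensitive to free fatty acids), 1590 nm, and a
weak feature near 1520 nm (O-H bend).  The acid value (AV, mg KOH per g
oil) quantifies free fatty acids; higher AV deepens the acid-related bands.

The generator builds, per sample,

    absorbance(lam) = baseline(lam) + sum_b amp_b(AV) * exp(-(lam-c_b)^2 / (2 w_b^2))
    reflectance(lam) = 10**(-absorbance) + noise

with a random per-sample baseline (offset, slope, mild curvature) and a
random interferent band — the multiplicative-scatter-like nuisance that
derivative and SNV pretreatments are designed to remove.  The amplitudes of
the 1330 nm and 1520 nm bands grow linearly with AV; the other bands do not.

Imaging scenes place a disk of oil (the evaporating dish) on a near-black
background.  Each oil pixel carries the sample spectrum modulated by a
spatially correlated texture field whose correlation length shrinks as
``texture_coupling * AV`` grows, so GLCM texture features carry an AV signal
when (and only when) ``texture_coupling > 0``.

All randomness flows through one explicitly passed seed; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import SpectrumSet, make_reference_table
from .envi import Hypercube, write_envi

#: Default AV range and skew reproduce a cohort with min 0.32, max 1.59 and
#: mean about 0.70 mg/g.
DEFAULT_AV_RANGE = (0.32, 1.59)
DEFAULT_N_SAMPLES = 153


@dataclass(frozen=True)
class TitrationRecord:
    """One KOH titration: concentration C (mol/L), volume V (mL), oil mass m (g)."""

    C: float
    V: float
    m: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.C) and np.isfinite(self.V) and np.isfinite(self.m)):
            raise ValueError("titration record values must be finite")
        if self.C <= 0:
            raise ValueError("KOH concentration C must be > 0")
        if self.V < 0:
            raise ValueError("titrant volume V must be >= 0")
        if self.m <= 0:
            raise ValueError("oil mass m must be > 0")


def titration_av(rec: TitrationRecord) -> float:
    """Acid value from a titration record: AV = 56.1 * C * V / m (mg KOH/g).

    56.1 g/mol is the molar mass of KOH; C*V/1000 mol of KOH neutralise the
    free fatty acids in m grams of oil, and the mg-per-g scaling cancels the
    mL/L factor.
    """
    return 56.1 * rec.C * rec.V / rec.m


def replicate_av(records) -> float:
    """Arithmetic mean AV over replicate titrations of one sample."""
    recs = list(records)
    if not recs:
        raise ValueError("no titration records")
    return float(np.mean([titration_av(r) for r in recs]))


@dataclass(frozen=True)
class SpectralSceneSpec:
    """Parameters of the synthetic oil spectrum and imaging scene.

    Units: wavelengths/band centers/widths in nm; ``av_coupling`` in
    absorbance per (mg/g); ``noise_sd`` in reflectance units;
    ``texture_coupling`` dimensionless in [0, 1].
    """

    wavelengths: np.ndarray = field(
        default_factory=lambda: np.linspace(870.0, 1720.0, 512)
    )
    band_centers: tuple[float, ...] = (1115.0, 1330.0, 1520.0, 1590.0)
    band_widths: tuple[float, ...] = (18.0, 12.0, 10.0, 15.0)
    band_amplitudes: tuple[float, ...] = (0.35, 0.18, 0.04, 0.30)
    av_coupling: tuple[float, ...] = (0.0, 0.16, 0.06, 0.0)
    band_amplitude_jitter: float = 0.012  # per-band absorbance jitter, per sample
    noise_sd: float = 0.001  # per-pixel reflectance noise
    texture_coupling: float = 0.0
    baseline_offset: tuple[float, float] = (0.25, 0.01)  # mean, sd
    baseline_slope: tuple[float, float] = (0.10, 0.015)  # absorbance across range
    baseline_curvature_sd: float = 0.02
    interferent_center: float = 1210.0
    interferent_width: float = 80.0
    interferent_amp_sd: float = 0.02
    scatter_sd: float = 0.01  # multiplicative smooth-scatter amplitude
    scatter_corr_nm: float = 200.0  # scatter correlation length along wavelength
    edge_noise_factor: float = 40.0  # noise inflation at the detector edges
    edge_noise_bands: int = 25  # bands per edge affected by the ramp
    texture_amplitude: float = 0.10
    texture_base_sigma: float = 2.5  # px, smoothing length at AV -> 0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.size < 2 or not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        k = len(self.band_centers)
        if not (len(self.band_widths) == len(self.band_amplitudes) == len(self.av_coupling) == k):
            raise ValueError("band parameter tuples must share a length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.texture_coupling <= 1.0:
            raise ValueError("texture_coupling must lie in [0, 1]")


def generate_reference_avs(
    n: int,
    av_min: float = DEFAULT_AV_RANGE[0],
    av_max: float = DEFAULT_AV_RANGE[1],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw n acid values from a right-skewed Beta(2, 5) scaled to [av_min, av_max].

    The Beta(2, 5) shape puts its mass low in the range with a long right
    tail, matching oil cohorts where most samples are fresh and a few are
    rancid; on the default range the expected mean is ~0.68 mg/g.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not av_min < av_max:
        raise ValueError("need av_min < av_max")
    rng = np.random.default_rng(seed)
    av = av_min + (av_max - av_min) * rng.beta(2.0, 5.0, size=n)
    ids = [f"oil{i + 1:03d}" for i in range(n)]
    return make_reference_table(ids, av)


def _absorbance(av: float, spec: SpectralSceneSpec, rng: np.random.Generator) -> np.ndarray:
    wl = spec.wavelengths
    u = (wl - wl[0]) / (wl[-1] - wl[0])  # 0..1 across the range
    b0 = rng.normal(*spec.baseline_offset)
    b1 = rng.normal(*spec.baseline_slope)
    b2 = rng.normal(0.0, spec.baseline_curvature_sd)
    absorb = b0 + b1 * u + b2 * (u - 0.5) ** 2
    for c, w, a0, g in zip(
        spec.band_centers, spec.band_widths, spec.band_amplitudes, spec.av_coupling
    ):
        amp = a0 + g * av + rng.normal(0.0, spec.band_amplitude_jitter)
        absorb = absorb + amp * np.exp(-((wl - c) ** 2) / (2.0 * w**2))
    amp = rng.normal(0.0, spec.interferent_amp_sd)
    absorb = absorb + amp * np.exp(
        -((wl - spec.interferent_center) ** 2) / (2.0 * spec.interferent_width**2)
    )
    return absorb


def noise_profile(spec: SpectralSceneSpec) -> np.ndarray:
    """Per-band noise multiplier: 1 in the interior, ramping up to
    ``edge_noise_factor`` at the first/last ``edge_noise_bands`` bands —
    the familiar sensitivity roll-off of InGaAs detector arrays."""
    p = spec.wavelengths.size
    prof = np.ones(p)
    w = min(spec.edge_noise_bands, p // 2)
    if w > 0 and spec.edge_noise_factor > 1:
        ramp = np.linspace(1.0, 0.0, w, endpoint=False)
        prof[:w] += (spec.edge_noise_factor - 1.0) * ramp
        prof[-w:] += (spec.edge_noise_factor - 1.0) * ramp[::-1]
    return prof


def _sample_reflectance(av: float, spec: SpectralSceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Noise-free sample spectrum: Beer-Lambert surrogate times smooth scatter.

    The multiplicative scatter field — a wavelength-smooth random curve with
    correlation length ``scatter_corr_nm`` — emulates sample-to-sample
    scattering/path-length variation; it is what SNV and derivative
    pretreatments are designed to suppress.
    """
    refl = 10.0 ** (-_absorbance(av, spec, rng))
    wl = spec.wavelengths
    delta = float(np.mean(np.diff(wl)))
    gain = np.ones(wl.size)
    if spec.scatter_sd > 0:
        rough = rng.standard_normal(wl.size)
        smooth = ndimage.gaussian_filter1d(rough, sigma=spec.scatter_corr_nm / delta, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            gain = gain + spec.scatter_sd * smooth / sd
    return refl * gain


def generate_oil_spectrum(
    av: float,
    spec: SpectralSceneSpec | None = None,
    seed: int | np.random.Generator = 0,
    noise_sd: float | None = None,
) -> np.ndarray:
    """One sample's mean reflectance spectrum for acid value ``av``.

    Reflectance is the noise-free sample spectrum plus N(0, noise_sd),
    clipped to (0, 1]; ``noise_sd`` defaults to the scene's per-pixel value
    (pass the ROI-averaged value for a mean spectrum).  With a fixed seed
    the nuisance draws are identical across ``av`` values, so reflectance
    at the 1330 nm band center decreases strictly with ``av``.
    """
    if av <= 0:
        raise ValueError("acid value must be > 0")
    spec = spec or SpectralSceneSpec()
    rng = np.random.default_rng(seed)
    refl = _sample_reflectance(av, spec, rng)
    sd = spec.noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        refl = refl + rng.normal(0.0, sd, size=refl.shape) * noise_profile(spec)
    return np.clip(refl, 1e-6, 1.0)


def _disk_mask(shape: tuple[int, int]) -> np.ndarray:
    """Ground-truth oil-disk mask: radius 0.35 * min(shape), centered."""
    rows, cols = shape
    radius = 0.35 * min(rows, cols)
    if 2 * radius > min(rows, cols):
        raise ValueError("oil disk does not fit in the frame")
    rr, cc = np.mgrid[0:rows, 0:cols]
    return (rr - (rows - 1) / 2) ** 2 + (cc - (cols - 1) / 2) ** 2 <= radius**2


def _texture_field(
    shape: tuple[int, int],
    mask: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spatially correlated field, zero mean / unit sd over the mask."""
    noise = rng.standard_normal(shape)
    fieldv = ndimage.gaussian_filter(noise, sigma=sigma)
    inside = fieldv[mask]
    sd = inside.std()
    if sd == 0:
        return np.zeros(shape)
    return (fieldv - inside.mean()) / sd


def generate_hypercube(
    av: float,
    spec: SpectralSceneSpec | None = None,
    shape: tuple[int, int] = (80, 80),
    seed: int = 0,
    bands: np.ndarray | None = None,
) -> tuple[Hypercube, np.ndarray]:
    """A disk-of-oil-on-dark-background scene plus its ground-truth mask.

    Every oil pixel carries the sample spectrum times ``1 + a * field`` where
    ``field`` is a smoothed Gaussian random field normalised to zero mean and
    unit variance over the disk, so the ROI-mean spectrum equals the sample
    spectrum up to pixel noise.  The field's smoothing length is
    ``texture_base_sigma / (1 + 2 * texture_coupling * av)``: rougher texture
    for higher AV when the coupling is on.

    ``bands`` restricts the cube to the given band indices; pixel noise is
    seeded per band, so a band-subset cube is exactly the corresponding
    slice of the full cube (texture extraction at a handful of selected
    wavelengths need not materialise all 512 planes).
    """
    if av <= 0:
        raise ValueError("acid value must be > 0")
    spec = spec or SpectralSceneSpec()
    rows, cols = shape
    if rows < 16 or cols < 16:
        raise ValueError("scene must be at least 16 x 16 pixels")
    rng = np.random.default_rng(seed)
    mask = _disk_mask((rows, cols))
    spectrum = _sample_reflectance(av, spec, rng)  # noise-free sample spectrum
    sigma = spec.texture_base_sigma / (1.0 + 2.0 * spec.texture_coupling * av)
    fieldv = _texture_field((rows, cols), mask, sigma, rng)

    band_idx = np.arange(spec.wavelengths.size) if bands is None else np.asarray(bands, dtype=int)
    modul = np.where(mask, 1.0 + spec.texture_amplitude * fieldv, 0.0)
    data = modul[:, :, None] * spectrum[band_idx][None, None, :]
    data = np.where(mask[:, :, None], data, 0.02)
    if spec.noise_sd > 0:
        prof = noise_profile(spec)
        for k, b in enumerate(band_idx):
            brng = np.random.default_rng([int(seed), int(b)])
            data[:, :, k] += brng.normal(0.0, spec.noise_sd * prof[b], size=(rows, cols))
    data = np.clip(data, 1e-6, 1.0)
    cube = Hypercube(
        data=data, wavelengths=spec.wavelengths[band_idx], metadata={"av": av}
    )
    return cube, mask


@dataclass(frozen=True)
class CubeSet:
    """Lazy per-sample imaging scenes; cubes are regenerated deterministically.

    Storing 150+ full cubes would be wasteful; each access rebuilds the same
    cube from the per-sample seed recorded at cohort generation.
    """

    avs: tuple[float, ...]
    seeds: tuple[int, ...]
    spec: SpectralSceneSpec
    shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.avs)

    def __getitem__(self, i: int) -> tuple[Hypercube, np.ndarray]:
        return generate_hypercube(self.avs[i], self.spec, self.shape, seed=self.seeds[i])

    def subcube(self, i: int, bands) -> tuple[Hypercube, np.ndarray]:
        """Sample i's scene restricted to the given band indices (sorted)."""
        return generate_hypercube(
            self.avs[i], self.spec, self.shape, seed=self.seeds[i], bands=bands
        )


@dataclass(frozen=True)
class Cohort:
    """A self-consistent synthetic cohort: spectra, scenes and AV references."""

    spectra: SpectrumSet
    cubes: CubeSet
    reference: pd.DataFrame

    @property
    def av(self) -> np.ndarray:
        return self.reference["av"].to_numpy()


def generate_cohort(
    n: int = DEFAULT_N_SAMPLES,
    spec: SpectralSceneSpec | None = None,
    seed: int = 0,
    av_range: tuple[float, float] = DEFAULT_AV_RANGE,
    cube_shape: tuple[int, int] = (80, 80),
) -> Cohort:
    """Generate ``n`` oil samples: reference AVs, mean spectra and scenes.

    The sample spectrum stored in ``spectra`` is the ROI-mean of that
    sample's scene by construction (texture field zero-mean over the disk):
    its noise is the per-pixel ``noise_sd`` divided by the square root of
    the disk pixel count, exactly what averaging the ROI delivers.
    Reproducible end to end under a fixed seed; per-sample sub-seeds make
    each sample's scene independent of cohort size and ordering.
    """
    if n < 10:
        raise ValueError("cohort needs at least 10 samples")
    spec = spec or SpectralSceneSpec()
    master = np.random.default_rng(seed)
    ref = generate_reference_avs(n, *av_range, seed=master.integers(2**31))
    sample_seeds = master.integers(2**31, size=n)
    mean_noise = spec.noise_sd / np.sqrt(_disk_mask(cube_shape).sum())
    X = np.empty((n, spec.wavelengths.size))
    for i, av in enumerate(ref["av"].to_numpy()):
        X[i] = generate_oil_spectrum(av, spec, seed=int(sample_seeds[i]), noise_sd=mean_noise)
    spectra = SpectrumSet(
        X=X, wavelengths=spec.wavelengths, sample_ids=tuple(ref["sample_id"])
    )
    cubes = CubeSet(
        avs=tuple(ref["av"]),
        seeds=tuple(int(s) for s in sample_seeds),
        spec=spec,
        shape=cube_shape,
    )
    return Cohort(spectra=spectra, cubes=cubes, reference=ref)


def save_cohort(cohort: Cohort, out_dir: str, write_cubes: bool = False) -> None:
    """Write a cohort to disk: reference CSV, spectra CSV, optional ENVI cubes."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    cohort.reference.rename(columns={"av": "av_mg_per_g"}).to_csv(
        os.path.join(out_dir, "reference.csv"), index=False
    )
    cohort.spectra.to_frame().to_csv(os.path.join(out_dir, "spectra.csv"), index=False)
    if write_cubes:
        for i, sid in enumerate(cohort.spectra.sample_ids):
            cube, _ = cohort.cubes[i]
            write_envi(
                Hypercube(
                    data=cube.data.astype(np.float32),
                    wavelengths=cube.wavelengths,
                ),
                os.path.join(out_dir, sid),
            )
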