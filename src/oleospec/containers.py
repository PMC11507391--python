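"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SpectrumSet:
    """A samples x wavelengths reflectance (or derivative) matrix.

    ``provenance`` records the pretreatments applied, in order, using the
    conventional short tags ("SG", "SNV", "1Der", "2Der", "Normalize",
    "Baseline"); it is append-only and renders into model labels such as
    "2Der-PLSR".
    """

    X: np.ndarray
    wavelengths: np.ndarray
    sample_ids: tuple[str, ...]
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "provenance", tuple(self.provenance))
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x wavelengths)")
        if X.shape[1] != wl.size:
            raise ValueError(
                f"column count {X.shape[1]} != wavelength count {wl.size}"
            )
        if X.shape[0] != len(self.sample_ids):
            raise ValueError("row count != number of sample ids")
        if not np.all(np.isfinite(X)):
            raise ValueError("SpectrumSet contains non-finite values")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    @property
    def label(self) -> str:
        """Pretreatment label, e.g. "2Der" or "SNV-SG"; "Raw" if untouched."""
        return "-".join(self.provenance) if self.provenance else "Raw"

    def with_data(self, X: np.ndarray, tag: str) -> "SpectrumSet":
        """Return a copy carrying new data and one more provenance tag."""
        return replace(self, X=X, provenance=self.provenance + (tag,))

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: sample_id, wavelength, reflectance."""
        n, p = self.X.shape
        return pd.DataFrame(
            {
                "sample_id": np.repeat(self.sample_ids, p),
                "wavelength": np.tile(self.wavelengths, n),
                "reflectance": self.X.ravel(),
            }
        )


def make_reference_table(sample_ids, av_values) -> pd.DataFrame:
    """Build the AV reference table (sample_id -> mg KOH per g oil).

    Values must be positive and finite, one entry per sample.
    """
    av = np.asarray(av_values, dtype=float)
    ids = [str(s) for s in sample_ids]
    if len(ids) != av.size:
        raise ValueError("sample_ids and av_values length mismatch")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in reference table")
    if not np.all(np.isfinite(av)) or np.any(av <= 0):
        raise ValueError("AV values must be finite and > 0")
    return pd.DataFrame({"sample_id": ids, "av": av})
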