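import numpy as np
import pytest

from oleospec import SpectrumSet
from oleospec.synthetic import SpectralSceneSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with texture-AV coupling, shared across tests."""
    spec = SpectralSceneSpec(texture_coupling=0.6)
    return generate_cohort(20, spec, seed=7, cube_shape=(48, 48))


@pytest.fixture
def random_spectra():
    rng = np.random.default_rng(11)
    wl = np.linspace(870.0, 1720.0, 64)
    X = 0.5 + 0.1 * rng.standard_normal((12, 64))
    ids = [f"s{i}" for i in range(12)]
    return SpectrumSet(X=X, wavelengths=wl, sample_ids=ids)
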