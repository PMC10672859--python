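import numpy as np
import pytest

from afnmr import (
    CohortConfig,
    SpectraMatrix,
    build_default_library,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def library():
    return build_default_library()


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort for fast pipeline-level tests."""
    return CohortConfig(n_term=10, n_preterm=6, points=2048, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    spectra, truth = simulate_cohort(small_config)
    return SpectraMatrix.from_spectra(spectra), truth


def lorentzian(ppm, center, gamma, area):
    """Reference Lorentzian profile, trapezoid-normalized to ``area``."""
    y = gamma**2 / ((ppm - center) ** 2 + gamma**2)
    return y * (area / np.trapezoid(y, ppm))
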