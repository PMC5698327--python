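import numpy as np
import pytest

from corneoraman import (CohortDepthModel, NoiseSpec, RunConfig, Region,
                         Spectrum, synth_cohort)
from corneoraman._gaussian import gaussian


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_spectrum(grid, bands=(), baseline=0.0, region=Region.FINGERPRINT,
                  noise=0.0, seed=0):
    """Helper: sum of (center, fwhm, amplitude) bands on a grid."""
    y = np.zeros_like(grid, dtype=float) + baseline
    for c, f, a in bands:
        y = y + gaussian(grid, c, f, a)
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0, noise, grid.size)
    return Spectrum(grid, y, region)


@pytest.fixture(scope="session")
def small_noiseless():
    """2 volunteers x 4 positions, zero additive noise (session cached)."""
    return synth_cohort(n_volunteers=2, n_positions=4, seed=7,
                        noise_spec=NoiseSpec.noiseless())


@pytest.fixture(scope="session")
def small_noiseless_results(small_noiseless):
    cohort, _ = small_noiseless
    return CohortDepthModel(cohort, RunConfig(seed=7)).fit()
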