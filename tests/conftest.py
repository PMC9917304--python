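import numpy as np
import pytest

from beecalim import (
    aliphatic_panel,
    default_geometry,
    generate_cohort,
)
from beecalim.processing import process_cohort


@pytest.fixture(scope="session")
def panel():
    return aliphatic_panel()


@pytest.fixture(scope="session")
def small_geometry():
    return default_geometry("AL", (48, 36))


@pytest.fixture(scope="session")
def noiseless_cohort(panel, small_geometry):
    """2 bees x full panel, no noise/bleach/jitter: exact forward model."""
    return generate_cohort(
        panel,
        n_bees=2,
        geometry=small_geometry,
        seed=11,
        bleach_rate=0.0,
        illumination_sigma=0.0,
        pixel_noise_sd=0.0,
        bee_gain_sd=0.0,
        bee_pattern_jitter=0.0,
        presentation_jitter=0.0,
    )


@pytest.fixture(scope="session")
def noisy_cohort(panel, small_geometry):
    """4 bees x full panel under the default noise conditions."""
    return generate_cohort(panel, n_bees=4, geometry=small_geometry, seed=7)


@pytest.fixture(scope="session")
def noisy_maps(noisy_cohort):
    return process_cohort(noisy_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
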