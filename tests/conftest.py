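import numpy as np
import pytest

from anxvbm import synthetic as syn


@pytest.fixture(scope="session")
def small_ispec():
    """Desk-scale image geometry shared across tests (~1.2k in-mask voxels)."""
    return syn.default_image_spec(grid_shape=(14, 16, 14), noise_sd=0.05)


@pytest.fixture(scope="session")
def small_cohort():
    return syn.generate_cohort(syn.CohortSpec(n_per_group=30, rng_seed=7))


@pytest.fixture(scope="session")
def patients(small_cohort):
    return small_cohort[small_cohort["group"].isin(["AD", "NAD"])].reset_index(drop=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
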