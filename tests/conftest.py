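import numpy as np
import pytest

from relaxroi.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The 14-patient synthetic cohort at its default study conditions."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def tiny_config():
    """A small, fast cohort configuration for structural tests."""
    return CohortConfig(
        n_enhancing=2,
        n_nonenhancing=2,
        grid_shape=(36, 36, 36),
        lesion_radius_range=(3.5, 4.5),
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
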