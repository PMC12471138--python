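import numpy as np
import pytest

from fundustex.synthetic_fundus import generate_cohort, load_preset

#: Matched-filter settings suited to the 256x256 synthetic scale.
SYNTH_MF = dict(sigma=1.5, length=7, n_orientations=12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def healthy_cohort():
    """Small seeded healthy cohort shared across tests."""
    return generate_cohort(load_preset("healthy", n_images=6, seed=7))


@pytest.fixture(scope="session")
def pathological_cohort():
    return generate_cohort(load_preset("pathological", n_images=6, seed=7))


@pytest.fixture(scope="session")
def one_sample(healthy_cohort):
    return healthy_cohort[0]
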