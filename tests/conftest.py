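import numpy as np
import pytest

from collidernet.imaging import generate_synthetic_pool
from collidernet.scm import sample_cohort


@pytest.fixture(scope="session")
def small_pool():
    """A modest synthetic pool shared by imaging/matching tests."""
    return generate_synthetic_pool(300, seed=11)


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for distributional checks of the structural model."""
    return sample_cohort(100_000, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
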