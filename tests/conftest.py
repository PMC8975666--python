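import numpy as np
import pytest

from prognet import synthetic


@pytest.fixture(scope="session")
def default_truth():
    return synthetic.make_ground_truth()


@pytest.fixture(scope="session")
def cohort5000(default_truth):
    """Discrete training cohort from the default seven-node truth."""
    return synthetic.sample_cohort(default_truth, 5000, seed=1, continuous=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
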