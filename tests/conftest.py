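import logging

import numpy as np
import pytest

logging.getLogger("ecatbrats").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model():
    """A small seeded model shared by read-only tests."""
    from ecatbrats.model import ECATBraTS, tiny_model_config
    return ECATBraTS(tiny_model_config(seed=7))


@pytest.fixture(scope="session")
def tiny_cases():
    from ecatbrats.training import tiny_cohort
    return tiny_cohort(2, seed=3)
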