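import logging

import numpy as np
import pytest
from hypothesis import settings

from olfdyad import synthetic

logging.getLogger("olfdyad").setLevel(logging.ERROR)

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at the default configuration."""
    return synthetic.generate_study_dataset(seed=7)
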