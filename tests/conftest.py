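import numpy as np
import pytest

import lvemulate as lv


@pytest.fixture(scope="session")
def small_dataset():
    """256 training + 4 test simulator runs, shared across tests (read-only)."""
    return lv.generate_dataset(256, 4)


@pytest.fixture(scope="session")
def tiny_dataset():
    """64 training + 2 test runs for the cheapest checks."""
    return lv.generate_dataset(64, 2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
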