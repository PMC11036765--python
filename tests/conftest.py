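import numpy as np
import pytest

from kneestrain import build_default_knee, initialize_reference_lengths


@pytest.fixture(scope="session")
def knee():
    """Initialized default knee, shared read-only across the session."""
    return initialize_reference_lengths(build_default_knee())


@pytest.fixture()
def fresh_knee():
    return initialize_reference_lengths(build_default_knee())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240423)
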