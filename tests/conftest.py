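import numpy as np
import pytest

from survcloak import veteran_like_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_137():
    """The default 137-subject synthetic cohort, shared across tests."""
    return veteran_like_fixture()
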