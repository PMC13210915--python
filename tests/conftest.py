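import numpy as np
import pytest

from legeit import forward


@pytest.fixture(scope="session")
def sens64():
    """Reference 64x64 sensitivity matrix (built once per session)."""
    return forward.build_sensitivity()


@pytest.fixture(scope="session")
def sens32():
    return forward.build_sensitivity(grid_size=32)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
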