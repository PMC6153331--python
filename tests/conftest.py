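import numpy as np
import pytest

from spikesnr.theory import TheoryParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def reference_params():
    """The parameter point the optimization table is computed at."""
    return TheoryParams(N=10_000, f=3.2, T=3.2, P=5, L=100.0)


@pytest.fixture
def small_params():
    """A desk-size problem for simulation-based tests."""
    return TheoryParams(N=400, f=3.2, T=3.2, P=2, L=100.0)
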