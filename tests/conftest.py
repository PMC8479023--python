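import numpy as np
import pytest

from dkinet import phantom
from dkinet.schemes import scanner_a_scheme, scanner_b_scheme


@pytest.fixture(scope="session")
def scheme_a():
    return scanner_a_scheme()


@pytest.fixture(scope="session")
def scheme_b():
    return scanner_b_scheme()


@pytest.fixture(scope="session")
def small_phantom():
    """One 16^3 phantom realization shared across read-only tests."""
    spec = phantom.PhantomSpec(shape=(16, 16, 16), seed=7)
    truth, maps, labels = phantom.generate_truth(spec)
    return spec, truth, maps, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
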