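import numpy as np
import pytest

from subsidydiet import simulate


@pytest.fixture(scope="session")
def table1():
    """Deterministic scat/cat fixture reproducing the published marginals."""
    return simulate.table1_fixture(seed=0)


@pytest.fixture(scope="session")
def sources():
    return simulate.tokunoshima_sources()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
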