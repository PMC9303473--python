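import numpy as np
import pytest

from bmis.synthetic import make_fixture


@pytest.fixture(scope="session")
def tiny_world():
    """2 countries x 5 years; envelopes small enough for brute-force oracles."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def small_world():
    """15 countries x 20 years, ~60 studies; the recovery-test scale."""
    return make_fixture("small")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230917)
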