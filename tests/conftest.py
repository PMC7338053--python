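import numpy as np
import pytest

from vactraffic.fixtures import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Small rendered movies plus ground truth, regenerated from seed 0."""
    return make_fixtures(0)


@pytest.fixture(scope="session")
def burst_fixture(fixtures):
    return fixtures["burst"]


@pytest.fixture(scope="session")
def delivery_fixture(fixtures):
    return fixtures["delivery"]


@pytest.fixture(scope="session")
def maturation_fixture(fixtures):
    return fixtures["maturation"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
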