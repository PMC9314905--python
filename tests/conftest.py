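import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import oneinflate as oi

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def vancouver() -> oi.CountFrequencies:
    return oi.load_fixture("vancouver")


@pytest.fixture(scope="session")
def rotterdam() -> oi.CountFrequencies:
    return oi.load_fixture("rotterdam")


@pytest.fixture(scope="session")
def bangkok() -> oi.CountFrequencies:
    return oi.load_fixture("bangkok")


@pytest.fixture(scope="session")
def tiny() -> oi.CountFrequencies:
    """Two singletons and one doubleton: small enough for exhaustive grids."""
    return oi.CountFrequencies({1: 2, 2: 1})


@pytest.fixture(scope="session")
def tiny3() -> oi.CountFrequencies:
    """Tiny instance with a tripleton, used by the quadrature cross-checks."""
    return oi.CountFrequencies({1: 2, 2: 1, 3: 1})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
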