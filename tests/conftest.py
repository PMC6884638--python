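import numpy as np
import pytest

from ncakin import InitialConditions, RateParams, build_network


@pytest.fixture(scope="session")
def base_params() -> RateParams:
    """The reference two-stage parameter set used throughout the suite."""
    return RateParams(k1=0.02, kon=10.0, koff=2.0, kr=0.2, s=10)


@pytest.fixture(scope="session")
def base_ic() -> InitialConditions:
    return InitialConditions.from_ratio(0.4, 100.0)


@pytest.fixture(scope="session")
def base_network(base_params, base_ic):
    return build_network(base_params, base_ic)


@pytest.fixture(scope="session")
def single_stage_params() -> RateParams:
    """Helix stage unreachable: pure chain growth at k1."""
    return RateParams(k1=0.02, kon=0.0, koff=0.0, kr=0.0, s=100_000)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
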