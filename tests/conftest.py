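import pytest
from hypothesis import settings

from vitisim.carbon_balance import CarbonBalanceParams

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from vitisim.synthetic import SyntheticConfig, generate_season


@pytest.fixture(scope="session")
def default_params() -> CarbonBalanceParams:
    return CarbonBalanceParams()


@pytest.fixture(scope="session")
def season():
    """One default synthetic VSP-like season, shared across tests."""
    return generate_season(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def season_shw():
    return generate_season(SyntheticConfig(seed=7, profile="shw"))
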