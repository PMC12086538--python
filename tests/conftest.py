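import pytest

from herdsim import (
    DEFAULT_PRICE_SLIDE,
    BudgetParams,
    SimulationSettings,
    StrategyConfig,
)


@pytest.fixture(scope="session")
def budget():
    return BudgetParams()


@pytest.fixture(scope="session")
def slide():
    return DEFAULT_PRICE_SLIDE


@pytest.fixture(scope="session")
def settings():
    return SimulationSettings()


@pytest.fixture(scope="session")
def bse_strategy():
    return StrategyConfig.bse()


@pytest.fixture(scope="session")
def nbse_strategy():
    return StrategyConfig.nbse()
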