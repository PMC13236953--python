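import numpy as np
import pytest

from whiteflypop import (
    DailyRates,
    SyntheticConfig,
    WhiteflyPopulationModel,
    generate_life_tables,
    life_table_to_daily_rates,
)


@pytest.fixture(scope="session")
def default_tables():
    """Synthetic life tables for the default fixture (seed 1)."""
    return generate_life_tables(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def rates28(default_tables):
    """Unadjusted daily rates at the 28 degC anchor."""
    return life_table_to_daily_rates(default_tables[28.0])


@pytest.fixture(scope="session")
def fitted():
    """Fitted model on the default synthetic fixture (q and gamma calibrated)."""
    return WhiteflyPopulationModel.from_synthetic(seed=1).fit()


@pytest.fixture()
def worked_rates():
    """The hand-checked rate set used across formula tests."""
    return DailyRates(
        temperature=28.0,
        r_egg=0.1, d_egg=0.05,
        r_nymph=0.0625, d_nymph=0.14375,
        r_pupa=0.2, d_pupa=0.05,
        d_adult=0.05,
        fecundity=5.0,
    )


@pytest.fixture(scope="session")
def constant_28(fitted):
    """A constant 28 degC series long enough for the default horizon."""
    return np.full(fitted.model.horizon, 28.0)
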