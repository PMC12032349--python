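import numpy as np
import pandas as pd
import pytest

from seacycle import SimulationConfig, simulate_community


@pytest.fixture(scope="session")
def small_config():
    """10-taxon guild-structured community, fortnightly 2011-2021."""
    return SimulationConfig.default(n_taxa=10, seed=1)


@pytest.fixture(scope="session")
def community(small_config):
    return simulate_community(small_config)


@pytest.fixture(scope="session")
def tables(community):
    return community[0]


@pytest.fixture(scope="session")
def truth(community):
    return community[1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def balanced_dates(n_years=4, start_year=2011):
    """One sample per month per year: a perfectly balanced design."""
    return pd.DatetimeIndex(
        [
            pd.Timestamp(year=start_year + y, month=m, day=15)
            for y in range(n_years)
            for m in range(1, 13)
        ]
    )
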