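import numpy as np
import pytest
from hypothesis import settings

from gms_costsim.strata import (
    Cohort,
    Gender,
    PopulationTable,
    RateTable,
    Region,
    StratumKey,
    all_strata,
    load_fixture,
)
from gms_costsim.synthetic_data import SyntheticConfig

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

EASTERN_M_0_11 = StratumKey(Region.EASTERN, Gender.MALE, Cohort.C0_11)


@pytest.fixture(scope="session")
def claims_rate_table() -> RateTable:
    return load_fixture("claims_rate_2007.csv")


@pytest.fixture(scope="session")
def avg_cost_table() -> RateTable:
    return load_fixture("avg_cost_2007.csv")


@pytest.fixture
def uniform_table():
    """Factory for constant-valued rate tables over the full stratum universe."""

    def make(kind: str, value: float, **kwargs) -> RateTable:
        return RateTable(kind, {k: value for k in all_strata()}, **kwargs)

    return make


@pytest.fixture
def uniform_population():
    def make(count: int, horizon: int = 2007) -> PopulationTable:
        return PopulationTable(horizon, {k: count for k in all_strata()})

    return make


@pytest.fixture
def small_config() -> SyntheticConfig:
    """One record per cell per month, single month: 160 rows, fast."""
    return SyntheticConfig(seed=7, records_per_cell_per_month=1, months=(1,))


@pytest.fixture(scope="session")
def default_claims_db():
    """The full default 192,000-row synthetic claims database (seed 11)."""
    from gms_costsim.synthetic_data import generate_claims_db

    return generate_claims_db(SyntheticConfig(seed=11))


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
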