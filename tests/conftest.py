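import numpy as np
import pytest
from hypothesis import settings

from strokecea import ModelParams, MortalityTable, uk_like_life_table

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams.defaults()


@pytest.fixture(scope="session")
def uk_table() -> MortalityTable:
    return uk_like_life_table()


@pytest.fixture(scope="session")
def zero_mortality() -> MortalityTable:
    """Nobody dies of background causes: isolates the annuity limits."""
    ages = np.arange(0, 140)
    return MortalityTable(ages, np.zeros(ages.size))
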