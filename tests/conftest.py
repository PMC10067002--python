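import numpy as np
import pandas as pd
import pytest

from healthvep.config import PopulationConfig
from healthvep import synthetic


@pytest.fixture(scope="session")
def small_population() -> pd.DataFrame:
    """A 3000-row default population shared across read-only tests."""
    return synthetic.generate_population(
        PopulationConfig(n_individuals=3000, seed=20240917))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
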