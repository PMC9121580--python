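import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ftndsim.dataset import ITEM_COLUMNS
from ftndsim.generator import default_config, generate_population

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_data(items, gender=None, smoke_where=None, smoking_allowed=None):
    """Build a schema-complete dataset from an item matrix (NaN = missing)."""
    items = np.asarray(items, dtype=float)
    n = items.shape[0]
    data = pd.DataFrame(items, columns=list(ITEM_COLUMNS))
    data.insert(0, "id", np.arange(n))
    data["gender"] = np.zeros(n, dtype=int) if gender is None else np.asarray(gender)
    data["smoke_where"] = (
        np.zeros(n, dtype=int) if smoke_where is None else np.asarray(smoke_where)
    )
    data["smoking_allowed"] = (
        np.zeros(n, dtype=int) if smoking_allowed is None else np.asarray(smoking_allowed)
    )
    return data


@pytest.fixture(scope="session")
def calibrated_population():
    """A mid-sized draw from the calibrated default generator."""
    return generate_population(default_config(), size=6000, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
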