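import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from aedes_thermal import synthetic_data as synth

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    return synth.default_truth()


@pytest.fixture(scope="session")
def egg_records(truth):
    return synth.simulate_egg_experiment(truth=truth, seed=0)


@pytest.fixture(scope="session")
def life_records(truth):
    return synth.simulate_life_history(truth=truth, seed=1)


@pytest.fixture(scope="session")
def monthly_raster():
    return synth.simulate_monthly_raster(shape=(20, 20), seed=2)


@pytest.fixture(scope="session")
def daily_series():
    return synth.simulate_daily_series(n_years=10, seed=3)


@pytest.fixture(scope="session")
def noiseless_tpc_points(truth):
    """Exact Briere-1 performance at the 16 rearing temperatures."""
    t = np.asarray(synth.LIFE_TEMPERATURES_C)
    return pd.DataFrame({
        "temperature_C": t,
        "performance": truth.briere_performance(t),
    })
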