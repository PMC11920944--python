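import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fluxdebt as fd
from fluxdebt import simulate

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free, gap-free one-year tower with a mid-year canopy drop."""
    return fd.SimConfig(start_date="2015-01-01", n_years=1,
                        landfall_date="2015-07-01", noise_sd=0.0,
                        missing_frac=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_sim(clean_cfg):
    return simulate.simulate_tower(clean_cfg)


@pytest.fixture(scope="session")
def debt_cfg():
    """Noise-free tower long enough for a reference year + 4 post years."""
    return fd.SimConfig(start_date="2015-01-01", n_years=6,
                        landfall_date="2016-09-10", noise_sd=0.0,
                        missing_frac=0.0, seed=5)


@pytest.fixture(scope="session")
def debt_sim(debt_cfg):
    return simulate.simulate_tower(debt_cfg)


@pytest.fixture()
def flux_frame():
    """Tiny handmade flux frame on a 30-min grid."""
    ts = pd.date_range("2018-01-01", periods=8, freq="30min")
    return pd.DataFrame({
        "timestamp": ts,
        "nee": [-150.0, -50.0, 0.0, 101.0, 5.0, np.nan, -3.0, 2.0],
        "rg": [0.0, 49.9, 50.0, 50.1, 600.0, 20.0, 0.0, 100.0],
        "tair": 20.0,
        "qc": "ok",
    })
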