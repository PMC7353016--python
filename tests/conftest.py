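import numpy as np
import pandas as pd
import pytest

from selmap import simulate
from selmap.variogram import ExponentialVariogramModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def field_model():
    """The cross-validated national serum Se field model used as
    simulation truth throughout."""
    return ExponentialVariogramModel(c0=2.51, c1=26.23, a=132.8)


@pytest.fixture
def survey_frame():
    """Small hand-built survey with known anatomy: 10 complete records,
    one missing longitude, one missing group, across 3 EAs."""
    n = 12
    df = pd.DataFrame({
        "person_id": [f"P{k:03d}" for k in range(n)],
        "ea_id": ["EA1"] * 4 + ["EA2"] * 4 + ["EA3"] * 4,
        "region": ["Oromia"] * 6 + ["Amhara"] * 6,
        "group": ["WRA"] * 6 + ["SAC"] * 3 + ["MEN"] * 3,
        "sex": ["F"] * 6 + ["M"] * 6,
        "residence": ["rural"] * 8 + ["urban"] * 4,
        "weight": np.linspace(0.5, 1.5, n),
        "lat": np.linspace(6.0, 12.0, n),
        "lon": np.linspace(36.0, 42.0, n),
        "serum_se_ugL": np.linspace(50.0, 160.0, n),
    })
    df.loc[10, "lon"] = np.nan     # missing GPS
    df.loc[11, "group"] = np.nan   # missing demographic
    return df


@pytest.fixture
def ea_samples(field_model, rng):
    """30 EA means drawn from the field model on a uniform layout."""
    cfg = simulate.SimulationConfig(seed=7, n_eas=30)
    locs = simulate.simulate_ea_locations(cfg)
    z = simulate.simulate_grf(field_model, locs["lat"], locs["lon"], 100.0, rng)
    return locs.assign(mean_se=z, n=1)
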