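import numpy as np
import pandas as pd
import pytest

from vinetrend import ClimateGrid, GeneratorConfig, generate_daily_climate


def make_constant_grid(year=1985, n_years=1, tmin=10.0, tmax=20.0, precip=1.0,
                       n_rows=2, n_cols=2):
    """A deterministic grid with constant daily values, for exact arithmetic checks."""
    dates = pd.date_range(f"{year}-01-01", f"{year + n_years - 1}-12-31", freq="D")
    shape = (len(dates), n_rows, n_cols)
    return ClimateGrid(
        dates=dates,
        tmin=np.full(shape, float(tmin)),
        tmax=np.full(shape, float(tmax)),
        precip=np.full(shape, float(precip)),
    )


@pytest.fixture(scope="session")
def michigan_grid():
    """Default Michigan-like synthetic climate on a small grid (shared, read-only)."""
    return generate_daily_climate(GeneratorConfig(n_rows=6, n_cols=6, seed=123))


@pytest.fixture
def tiny_config():
    """A fast, fully stochastic generator config for structural tests."""
    return GeneratorConfig(n_years=4, start_year=2000, n_rows=3, n_cols=2, seed=5)
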