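import numpy as np
import pandas as pd
import pytest

from bambooflux.synthetic import (
    TrueParameterTrajectory,
    generate_fluxes,
    generate_meteorology,
)


@pytest.fixture(scope="session")
def noiseless_quarter():
    """90 days of gap-free, noise-free fluxes from constant parameters."""
    met = generate_meteorology(90, seed=11)
    truth = TrueParameterTrajectory.constant(
        90, alpha=0.003, pmax=0.7, r_ref=0.08, e0=309.0, noise_sd=0.0, seed=11
    )
    records, truth_df = generate_fluxes(met, truth)
    return records, truth_df, truth


@pytest.fixture(scope="session")
def noisy_year():
    """A full noisy calendar year with seasonal parameter trajectories."""
    from bambooflux.synthetic import seasonal_trajectory

    days = 365
    truth = seasonal_trajectory(days, start="2011-01-01", noise_sd=0.05, seed=7)
    met = generate_meteorology(days, seed=7, start="2011-01-01")
    records, truth_df = generate_fluxes(met, truth)
    return records, truth_df, truth


def make_series(values, start="2015-06-01", **extra):
    """A minimal half-hourly frame holding one meteorological variable."""
    values = np.asarray(values, dtype=float)
    index = pd.date_range(start, periods=len(values), freq="30min", name="timestamp")
    frame = pd.DataFrame({"nee": np.nan, "par": 0.0, "ta": values}, index=index)
    for k, v in extra.items():
        frame[k] = v
    return frame
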