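import numpy as np
import pytest
import xarray as xr

from climhealth.synth import (
    ClimateScenarioSpec,
    EconomySpec,
    PopulationSpec,
    generate_climate,
    generate_io_table,
    generate_population,
)


def make_series_grid(values, n_lat=1, n_lon=1, years=None):
    """Wrap a 1-D daily series into a (time, lat, lon) tmax DataArray."""
    v = np.asarray(values, dtype=float)
    data = np.broadcast_to(v[:, None, None], (len(v), n_lat, n_lon)).copy()
    coords = {
        "time": np.arange(len(v)),
        "lat": np.arange(n_lat, dtype=float),
        "lon": np.arange(n_lon, dtype=float),
    }
    if years is not None:
        coords["year"] = ("time", np.asarray(years))
    return xr.DataArray(data, dims=("time", "lat", "lon"), coords=coords, name="tmax")


@pytest.fixture(scope="session")
def warming_climate():
    return generate_climate(
        ClimateScenarioSpec(
            shape=(3, 3),
            baseline_years=(1986, 2005),
            analysis_years=(2006, 2019),
            base_temp_mean=24.0,
            seasonal_amplitude=8.0,
            trend_per_decade=0.5,
            noise_sd=2.0,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def population_grid():
    return generate_population(
        PopulationSpec(shape=(3, 3), total=90_000, elderly_fraction=0.1, seed=7)
    )


@pytest.fixture(scope="session")
def small_economy():
    return generate_io_table(EconomySpec(n_sectors=4, interdependence=0.5, seed=3))
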