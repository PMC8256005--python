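import numpy as np
import pandas as pd
import pytest
import xarray as xr

from cardui.grids import GridField
from cardui.synthetic import WindScenarioConfig, gen_wind_fields
from cardui.trajectories import AtmosphereFields


@pytest.fixture
def balanced_visits() -> pd.DataFrame:
    """Two sites x two years with exactly multiplicative counts [[2,8],[4,16]]."""
    return pd.DataFrame(
        {
            "site_id": ["a", "a", "b", "b"],
            "date": ["2000-04-01", "2001-04-01", "2000-04-01", "2001-04-01"],
            "count": [2, 8, 4, 16],
            "transect_length_m": [1000.0] * 4,
            "region": ["NE Spain"] * 4,
        }
    )


def make_field(values, lats, lons, times, name="ndvi", units="1") -> GridField:
    da = xr.DataArray(
        np.asarray(values, dtype=float),
        coords={"time": pd.DatetimeIndex(times), "lat": lats, "lon": lons},
        dims=("time", "lat", "lon"),
        name=name,
    )
    return GridField(da, units)


@pytest.fixture(scope="session")
def calm_atmosphere() -> AtmosphereFields:
    cfg = WindScenarioConfig(
        scenario="uniform", uniform_uv=(0.0, 0.0), n_days=8, spacing=2.0
    )
    wb = gen_wind_fields(cfg, 0)
    return AtmosphereFields(wb.u, wb.v, wb.t)


def uniform_atmosphere(u: float, v: float, temp: float = 20.0, n_days: int = 8):
    cfg = WindScenarioConfig(
        scenario="uniform",
        uniform_uv=(u, v),
        uniform_temp=temp,
        n_days=n_days,
        spacing=2.0,
    )
    wb = gen_wind_fields(cfg, 0)
    return AtmosphereFields(wb.u, wb.v, wb.t)
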