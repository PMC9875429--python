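import numpy as np
import pandas as pd
import pytest

from aircrossover.grids import GridField


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_field(values, *, lats=None, lons=None, start="2015-01-01", name="pm25"):
    """Small GridField helper: values (n_days, n_lat, n_lon)."""
    values = np.asarray(values, dtype=float)
    n_d, n_la, n_lo = values.shape
    lats = np.asarray(lats) if lats is not None else 30.0 + 0.1 * np.arange(n_la)
    lons = np.asarray(lons) if lons is not None else 110.0 + 0.1 * np.arange(n_lo)
    dates = np.arange(np.datetime64(start, "D"), np.datetime64(start, "D") + np.timedelta64(n_d, "D"))
    return GridField(name=name, lats=lats, lons=lons, dates=dates, values=values)


@pytest.fixture
def affine_field():
    """4x4 field affine in lat and lon: v = 2*lat + 3*lon + 1, 3 days."""
    lats = 30.0 + 0.1 * np.arange(4)
    lons = 110.0 + 0.1 * np.arange(4)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    plane = 2.0 * glat + 3.0 * glon + 1.0
    return make_field(np.broadcast_to(plane, (3, 4, 4)).copy(), lats=lats, lons=lons)


@pytest.fixture
def tiny_strata():
    """Two hand-built strata with one covariate for likelihood checks."""
    return pd.DataFrame(
        {
            "stratum_id": ["a"] * 4 + ["b"] * 4,
            "date": pd.date_range("2015-01-07", periods=4, freq="7D").tolist() * 2,
            "is_case": [1, 0, 0, 0, 0, 1, 0, 0],
            "x": [1.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0],
        }
    )
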