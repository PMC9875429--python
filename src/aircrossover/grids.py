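"""Gridded daily environmental fields and grid-to-point exposure assessment.

A :class:`GridField` holds daily values of one variable (a pollutant or a
meteorological variable) on a regular latitude/longitude grid of cell
*centers*.  Exposure at a residential point is estimated by bilinear
interpolation over the four surrounding cell centers; when fewer than four
cells carry a value on a given day, the remaining bilinear weights are
re-distributed so they sum to one.  Lagged exposure metrics (single lags and
moving averages such as "MA 0-1") are computed from the interpolated daily
series.  Missing values are never imputed: a lag window touching a missing
day yields a missing result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GridField",
    "LagSpec",
    "read_grid",
    "write_grid_csv",
    "write_grid_netcdf",
    "bilinear_weights",
    "renormalize_weights",
    "bilinear_interpolate",
    "interpolate_points",
    "max_8h_mean",
    "lagged_value",
    "lagged_points",
]

_DAY = np.timedelta64(1, "D")


class GridStructureError(ValueError):
    """Raised when a grid file or array violates the regular-grid contract."""


def _check_axis(centers: np.ndarray, name: str) -> float:
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 1 or centers.size < 2:
        raise GridStructureError(f"{name} axis needs at least two centers")
    steps = np.diff(centers)
    if np.any(steps <= 0):
        raise GridStructureError(f"{name} axis must be strictly ascending")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise GridStructureError(f"{name} axis has non-uniform spacing")
    return float(steps[0])


@dataclass
class GridField:
    """Daily values of one variable on a regular lat/lon grid of cell centers.

    ``values`` has shape (n_days, n_lat, n_lon); missing cells are NaN.
    The date axis must be gap-free consecutive calendar days.
    """

    name: str
    lats: np.ndarray
    lons: np.ndarray
    dates: np.ndarray
    values: np.ndarray
    units: str = ""
    dlat: float = field(init=False, repr=False)
    dlon: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.values = np.asarray(self.values, dtype=float)
        self.dlat = _check_axis(self.lats, "latitude")
        self.dlon = _check_axis(self.lons, "longitude")
        if self.dates.ndim != 1 or self.dates.size == 0:
            raise GridStructureError("date axis is empty")
        if self.dates.size > 1:
            gaps = np.diff(self.dates)
            if np.any(gaps != _DAY):
                raise GridStructureError("date axis has gaps")
        expected = (self.dates.size, self.lats.size, self.lons.size)
        if self.values.shape != expected:
            raise GridStructureError(
                f"value array shape {self.values.shape} does not match axes {expected}"
            )

    @property
    def start(self) -> np.datetime64:
        return self.dates[0]

    def date_index(self, days: np.ndarray | np.datetime64) -> np.ndarray:
        """Integer offsets of ``days`` on the date axis; out-of-range → error."""
        days = np.asarray(days, dtype="datetime64[D]")
        idx = (days - self.start) / _DAY
        idx = idx.astype(np.int64)
        if np.any(idx < 0) or np.any(idx >= self.dates.size):
            raise KeyError(f"day outside the date axis of field '{self.name}'")
        return idx


@dataclass(frozen=True)
class LagSpec:
    """A single-lag or moving-average exposure window.

    ``lag k``   : value k days before the event day (k0 == k1 == k).
    ``MA k0-k1``: arithmetic mean over event_day - k1 ... event_day - k0.
    """

    kind: str  # "single" | "ma"
    k0: int
    k1: int

    def __post_init__(self) -> None:
        if self.kind not in ("single", "ma"):
            raise ValueError("kind must be 'single' or 'ma'")
        if self.k0 < 0 or self.k1 < self.k0:
            raise ValueError("need 0 <= k0 <= k1")
        if self.kind == "single" and self.k0 != self.k1:
            raise ValueError("single lag requires k0 == k1")
        if self.kind == "ma" and self.k1 - self.k0 + 1 < 2:
            raise ValueError("moving average needs a window of >= 2 days")

    @classmethod
    def single(cls, k: int) -> "LagSpec":
        return cls("single", k, k)

    @classmethod
    def moving_average(cls, k0: int, k1: int) -> "LagSpec":
        return cls("ma", k0, k1)

    @classmethod
    def parse(cls, text: str) -> "LagSpec":
        """Parse 'lag 2' / 'lag2' / 'MA 0-1' / 'ma0-4' style labels."""
        t = text.strip().lower().replace(" ", "")
        if t.startswith("ma"):
            k0, k1 = t[2:].split("-")
            return cls.moving_average(int(k0), int(k1))
        if t.startswith("lag"):
            body = t[3:]
            if "-" in body:
                k0, k1 = body.split("-")
                return cls.moving_average(int(k0), int(k1))
            return cls.single(int(body))
        raise ValueError(f"cannot parse lag spec {text!r}")

    @property
    def label(self) -> str:
        if self.kind == "single":
            return f"lag {self.k0}"
        return f"MA {self.k0}-{self.k1}"

    @property
    def tag(self) -> str:
        """Short identifier usable in column names (e.g. lag2, ma01)."""
        if self.kind == "single":
            return f"lag{self.k0}"
        return f"ma{self.k0}{self.k1}"

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.k0, self.k1 + 1)


# ---------------------------------------------------------------------------
# I/O: NetCDF (via xarray) and long CSV dialects
# ---------------------------------------------------------------------------

def read_grid(path: str | Path, variable: str) -> GridField:
    """Read one variable from a NetCDF (time/lat/lon) or long CSV file.

    The CSV dialect has columns date, lat, lon, value (an optional
    ``variable`` column is filtered on).  Both dialects yield identical
    arrays for the same field.
    """
    path = Path(path)
    if path.suffix in (".nc", ".cdf", ".netcdf"):
        return _read_grid_netcdf(path, variable)
    return _read_grid_csv(path, variable)


def _read_grid_netcdf(path: Path, variable: str) -> GridField:
    import xarray as xr

    with xr.open_dataset(path) as ds:
        if variable not in ds:
            raise KeyError(f"variable {variable!r} not in {path}")
        da = ds[variable].transpose("time", "lat", "lon")
        fld = GridField(
            name=variable,
            lats=da["lat"].values,
            lons=da["lon"].values,
            dates=da["time"].values.astype("datetime64[D]"),
            values=da.values.astype(float),
            units=str(da.attrs.get("units", "")),
        )
    return fld


def _read_grid_csv(path: Path, variable: str) -> GridField:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for need in ("date", "lat", "lon", "value"):
        if need not in cols:
            raise GridStructureError(f"CSV grid file lacks column {need!r}")
    if "variable" in cols:
        df = df[df[cols["variable"]] == variable]
        if df.empty:
            raise KeyError(f"variable {variable!r} not in {path}")
    dates = pd.to_datetime(df[cols["date"]]).values.astype("datetime64[D]")
    lats = np.sort(df[cols["lat"]].unique())
    lons = np.sort(df[cols["lon"]].unique())
    udates = np.sort(np.unique(dates))
    values = np.full((udates.size, lats.size, lons.size), np.nan)
    ti = np.searchsorted(udates, dates)
    yi = np.searchsorted(lats, df[cols["lat"]].values)
    xi = np.searchsorted(lons, df[cols["lon"]].values)
    values[ti, yi, xi] = df[cols["value"]].values
    return GridField(name=variable, lats=lats, lons=lons, dates=udates, values=values)


def write_grid_csv(fld: GridField, path: str | Path) -> None:
    """Write the long CSV dialect (date, lat, lon, value); NaN rows skipped."""
    ti, yi, xi = np.nonzero(np.isfinite(fld.values))
    df = pd.DataFrame(
        {
            "date": fld.dates[ti].astype("datetime64[s]").astype(str),
            "lat": fld.lats[yi],
            "lon": fld.lons[xi],
            "value": fld.values[ti, yi, xi],
            "variable": fld.name,
        }
    )
    df.to_csv(path, index=False)


def write_grid_netcdf(fld: GridField, path: str | Path) -> None:
    import xarray as xr

    da = xr.DataArray(
        fld.values,
        dims=("time", "lat", "lon"),
        coords={
            "time": fld.dates.astype("datetime64[ns]"),
            "lat": fld.lats,
            "lon": fld.lons,
        },
        name=fld.name,
        attrs={"units": fld.units},
    )
    # NETCDF3 via the scipy engine keeps the on-disk format dependency-light.
    da.to_dataset().to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# Bilinear interpolation to points
# ---------------------------------------------------------------------------

class OutOfDomainError(ValueError):
    """Point farther than half a cell spacing outside the hull of centers."""


def _axis_cell(centers: np.ndarray, spacing: float, coord: np.ndarray):
    """Lower cell index and clipped fractional position along one axis.

    Points within half a spacing outside the hull of centers are clamped to
    the nearest edge cell pair; farther points raise OutOfDomainError.
    """
    coord = np.asarray(coord, dtype=float)
    tol = 1e-9 * max(1.0, spacing)
    lo = centers[0] - spacing / 2 - tol
    hi = centers[-1] + spacing / 2 + tol
    if np.any(coord < lo) or np.any(coord > hi):
        raise OutOfDomainError(
            "point farther than half a grid spacing outside the grid hull"
        )
    i = np.clip(np.searchsorted(centers, coord, side="right") - 1, 0, centers.size - 2)
    t = np.clip((coord - centers[i]) / spacing, 0.0, 1.0)
    return i.astype(np.int64), t


def bilinear_weights(fld: GridField, lat, lon):
    """Corner indices and bilinear weights for point(s) (lat, lon).

    Returns (ilat, jlon, w) where ilat/jlon index the lower-left corner and
    ``w`` has shape (..., 4) ordered (ll, lr, ul, ur); weights sum to 1 and
    lie in [0, 1].
    """
    i, ty = _axis_cell(fld.lats, fld.dlat, lat)
    j, tx = _axis_cell(fld.lons, fld.dlon, lon)
    w = np.stack(
        [(1 - ty) * (1 - tx), (1 - ty) * tx, ty * (1 - tx), ty * tx], axis=-1
    )
    return i, j, w


def renormalize_weights(weights: np.ndarray, available: np.ndarray):
    """Re-distribute bilinear weights over the available corners.

    Unavailable corners get weight 0 and the rest are rescaled to sum to 1.
    With all four corners available the weights are returned unchanged; with
    none available the return value is ``None`` (a missing-value signal, not
    an exception — the observation day is flagged missing downstream).
    """
    weights = np.asarray(weights, dtype=float)
    available = np.asarray(available, dtype=bool)
    if not available.any():
        return None
    if available.all():
        return weights.copy()
    out = np.where(available, weights, 0.0)
    return out / out.sum()


def bilinear_interpolate(fld: GridField, lat: float, lon: float, day) -> float:
    """Interpolated value of ``fld`` at one point and day.

    Weighted average of the nearest four grid-cell centers with standard
    bilinear weights; missing corners trigger weight re-distribution.  All
    four corners missing → NaN.
    """
    i, j, w = bilinear_weights(fld, lat, lon)
    t = int(fld.date_index(np.datetime64(day, "D")))
    corners = np.array(
        [
            fld.values[t, i, j],
            fld.values[t, i, j + 1],
            fld.values[t, i + 1, j],
            fld.values[t, i + 1, j + 1],
        ]
    )
    w2 = renormalize_weights(w, np.isfinite(corners))
    if w2 is None:
        return float("nan")
    return float(np.nansum(w2 * corners))


def interpolate_points(fld: GridField, lats, lons, tidx):
    """Vectorised interpolation at (lat, lon, date-index) triples.

    ``tidx`` may contain negative entries (before the date axis start);
    those yield NaN with 0 grids used.  Returns (values, n_grids_used).
    """
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    tidx = np.atleast_1d(np.asarray(tidx, dtype=np.int64))
    i, j, w = bilinear_weights(fld, lats, lons)
    valid_t = (tidx >= 0) & (tidx < fld.dates.size)
    ts = np.where(valid_t, tidx, 0)
    corners = np.stack(
        [
            fld.values[ts, i, j],
            fld.values[ts, i, j + 1],
            fld.values[ts, i + 1, j],
            fld.values[ts, i + 1, j + 1],
        ],
        axis=-1,
    )
    finite = np.isfinite(corners)
    # Treat corners with (numerically) zero weight as absent so that the
    # "number of grids used" bookkeeping reflects contributing cells only.
    contributing = finite & (w > 1e-12)
    wmask = np.where(contributing, w, 0.0)
    wsum = wmask.sum(axis=-1)
    n_used = contributing.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(
            (wsum > 0) & valid_t,
            np.nansum(wmask * np.where(finite, corners, 0.0), axis=-1) / np.where(wsum > 0, wsum, 1.0),
            np.nan,
        )
    n_used = np.where(valid_t, n_used, 0)
    return vals, n_used


# ---------------------------------------------------------------------------
# Daily metrics
# ---------------------------------------------------------------------------

def max_8h_mean(hourly) -> float:
    """Daily maximum 8-hour mean from 24 within-day hourly values.

    Windows are the 17 blocks of 8 consecutive hours that do not cross
    midnight.  A window containing any missing hour is skipped; if every
    window is missing the result is NaN.
    """
    hourly = np.asarray(hourly, dtype=float)
    if hourly.shape != (24,):
        raise ValueError("max_8h_mean needs exactly 24 hourly values")
    windows = np.lib.stride_tricks.sliding_window_view(hourly, 8)
    means = windows.mean(axis=1)  # NaN where any hour missing
    if not np.isfinite(means).any():
        return float("nan")
    return float(np.nanmax(means))


def lagged_value(dates, values, event_day, spec: LagSpec) -> float:
    """Lagged exposure metric from one point's daily series.

    Single lag → the value ``k0`` days before ``event_day``; moving average
    → the mean over days event_day-k1 ... event_day-k0.  Any missing day in
    the window, or a window extending before the series start, gives NaN.
    """
    dates = np.asarray(dates, dtype="datetime64[D]")
    values = np.asarray(values, dtype=float)
    idx = int((np.datetime64(event_day, "D") - dates[0]) / _DAY)
    lo, hi = idx - spec.k1, idx - spec.k0
    if lo < 0 or hi >= dates.size:
        return float("nan")
    window = values[lo : hi + 1]
    if not np.isfinite(window).all():
        return float("nan")
    return float(window.mean())


def lagged_points(fld: GridField, lats, lons, days, spec: LagSpec):
    """Vectorised lagged metric of a field at (lat, lon, day) triples.

    Interpolates each lag day and averages over the window; any missing or
    pre-axis day in the window makes the result NaN.  Returns
    (values, n_grids_used) where n_grids_used is the minimum over the
    window (0 when the result is missing).
    """
    days = np.asarray(days, dtype="datetime64[D]")
    tidx = ((days - fld.start) / _DAY).astype(np.int64)
    total = np.zeros(tidx.shape, dtype=float)
    n_min = np.full(tidx.shape, 5, dtype=np.int64)
    ok = np.ones(tidx.shape, dtype=bool)
    for off in spec.offsets:
        v, n = interpolate_points(fld, lats, lons, tidx - off)
        ok &= np.isfinite(v)
        total = total + np.where(np.isfinite(v), v, 0.0)
        n_min = np.minimum(n_min, n)
    nwin = spec.k1 - spec.k0 + 1
    vals = np.where(ok, total / nwin, np.nan)
    return vals, np.where(ok, n_min, 0)
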