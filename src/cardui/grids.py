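"""Gridded environmental fields, region geometries, and covariate series.

Environmental drivers (NDVI greenness, precipitation, temperature, 850 hPa
winds) arrive as lat-lon(-level-time) grids. This module reads them from
NetCDF, averages them over ecoregions/kernel areas and month windows, and
standardizes the resulting yearly covariate series for modeling.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from scipy import stats
from shapely.geometry import MultiPolygon, Polygon, box, shape, mapping
from shapely.ops import unary_union

from .errors import DegenerateCovariateError, EmptyRegionError, GridFormatError

log = logging.getLogger(__name__)

_AXIS_ALIASES = {
    "lat": ("lat", "latitude", "y"),
    "lon": ("lon", "longitude", "x"),
    "time": ("time", "t", "date"),
    "level": ("level", "lev", "height", "altitude", "alt", "plev", "z"),
}

#: valid NDVI range after normalization
NDVI_RANGE = (-0.3, 1.0)


def _canonical_dims(da: xr.DataArray) -> xr.DataArray:
    """Rename recognised coordinate axes to lat/lon/time/level."""
    renames = {}
    for canon, aliases in _AXIS_ALIASES.items():
        for dim in da.dims:
            if str(dim).lower() in aliases and dim != canon:
                renames[dim] = canon
    return da.rename(renames)


def normalize_lon(lon):
    """Map longitudes into [-180, 180)."""
    return ((np.asarray(lon, dtype=float) + 180.0) % 360.0) - 180.0


@dataclass
class GridField:
    """A named environmental variable on a lat-lon(-level-time) grid.

    ``data`` carries dims ``(time[, level], lat, lon)`` with lat/lon strictly
    ascending and longitudes in [-180, 180). Missing values are NaN and are
    respected by every reduction.
    """

    data: xr.DataArray
    units: str = ""

    def __post_init__(self) -> None:
        da = _canonical_dims(self.data)
        for ax in ("lat", "lon"):
            if ax not in da.dims:
                raise GridFormatError(f"field {da.name!r} lacks a {ax} axis")
        if "time" not in da.dims:
            raise GridFormatError(f"field {da.name!r} lacks a time axis")
        lon = normalize_lon(da["lon"].values)
        da = da.assign_coords(lon=lon)
        order = [d for d in ("time", "level", "lat", "lon") if d in da.dims]
        da = da.transpose(*order).sortby("lat").sortby("lon")
        if "level" in da.dims:
            da = da.sortby("level")
        for ax in ("lat", "lon"):
            vals = da[ax].values
            if len(vals) > 1 and not np.all(np.diff(vals) > 0):
                raise GridFormatError(f"{ax} axis is not strictly monotone")
        if not self.units:
            self.units = str(da.attrs.get("units", ""))
        self.data = da

    @property
    def name(self) -> str:
        return str(self.data.name)

    @property
    def lats(self) -> np.ndarray:
        return self.data["lat"].values

    @property
    def lons(self) -> np.ndarray:
        return self.data["lon"].values

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["time"].values)

    @property
    def levels(self) -> np.ndarray | None:
        return self.data["level"].values if "level" in self.data.dims else None

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.times.year)

    def sel_year_month(self, year: int, month: int) -> xr.DataArray:
        t = self.times
        sel = (t.year == year) & (t.month == month)
        if not sel.any():
            raise KeyError(f"no time slice for {year}-{month:02d}")
        return self.data.isel(time=np.nonzero(sel)[0]).mean("time", skipna=True)

    def to_netcdf(self, path) -> None:
        ds = self.data.to_dataset(name=self.name or "field")
        ds[self.name or "field"].attrs["units"] = self.units
        ds.to_netcdf(path, engine="scipy")


def to_monthly(field: GridField) -> GridField:
    """Collapse a sub-monthly time axis to calendar months by arithmetic mean.

    Half-monthly NDVI composites become monthly fields; each month's layers
    are averaged with equal weight.
    """
    da = field.data
    t = field.times
    key = pd.DatetimeIndex(t.to_period("M").to_timestamp())
    da = da.assign_coords(time=key).groupby("time").mean(skipna=True)
    return GridField(da.rename(field.name), units=field.units)


def load_grid(path, variable: str, *, monthly: bool = False) -> GridField:
    """Read one variable from a NetCDF file into a :class:`GridField`.

    Axes are renamed to lat/lon/time[/level] and sorted ascending; units are
    taken from variable attributes. ``monthly=True`` averages a sub-monthly
    (e.g. half-monthly composite) time axis down to calendar months.
    """
    try:
        ds = xr.open_dataset(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise GridFormatError(f"cannot read {path}: {exc}") from exc
    if variable not in ds:
        raise GridFormatError(
            f"variable {variable!r} not in {path} (has: {sorted(ds.data_vars)})"
        )
    fld = GridField(ds[variable].load())
    ds.close()
    return to_monthly(fld) if monthly else fld


@dataclass
class RegionGeometry:
    """A named region: polygon(s) or an explicit set of grid squares.

    ``subregions`` optionally partitions the region (e.g. northern/southern).
    """

    name: str
    geometry: Polygon | MultiPolygon
    subregions: dict[str, Polygon | MultiPolygon] | None = None

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise ValueError(f"region {self.name!r} has empty geometry")

    @classmethod
    def from_squares(
        cls, name: str, corners: Iterable[tuple[float, float]], square_deg: float = 1.0
    ) -> "RegionGeometry":
        """Build a region from SW corners of axis-aligned squares."""
        boxes = [box(x, y, x + square_deg, y + square_deg) for x, y in corners]
        if not boxes:
            raise ValueError(f"region {name!r} has no squares")
        return cls(name, unary_union(boxes))

    @classmethod
    def from_geojson(cls, path, name: str | None = None) -> "RegionGeometry":
        with open(path) as fh:
            gj = json.load(fh)
        geoms, subregions = [], {}
        feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        for feat in feats:
            geom = shape(feat["geometry"] if "geometry" in feat else feat)
            geoms.append(geom)
            sub = (feat.get("properties") or {}).get("subregion")
            if sub:
                subregions.setdefault(sub, []).append(geom)
        merged = unary_union(geoms)
        subs = {k: unary_union(v) for k, v in subregions.items()} or None
        return cls(name or gj.get("name", "region"), merged, subs)

    def to_geojson(self, path) -> None:
        gj = {
            "type": "Feature",
            "properties": {"name": self.name},
            "geometry": mapping(self.geometry),
        }
        with open(path, "w") as fh:
            json.dump(gj, fh)

    def contains_mask(self, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
        """Boolean (lat, lon) mask: cell centers inside the region."""
        lon2, lat2 = np.meshgrid(lons, lats)
        return shapely.contains_xy(self.geometry, lon2, lat2)


def regional_mean(
    field: GridField,
    region: RegionGeometry,
    months: Sequence[int],
    year: int,
    *,
    cos_lat_weights: bool = False,
) -> float:
    """Mean of a field over a region across a month window of one year.

    Computed as the mean over months of the per-month regional means; within
    a month, unmasked cells whose centers fall inside the region are averaged
    (unweighted by default; cos-latitude weighting is optional).
    """
    if not months:
        raise ValueError("months must be nonempty")
    if year not in field.years:
        raise ValueError(f"year {year} outside field time span")
    mask = region.contains_mask(field.lons, field.lats)
    if not mask.any():
        raise EmptyRegionError(f"region {region.name!r} intersects no grid cells")
    w = np.cos(np.deg2rad(field.lats))[:, None] * np.ones_like(mask, dtype=float)
    monthly = []
    for m in sorted(set(months)):
        layer = field.sel_year_month(year, m).values
        if "level" in field.data.dims:
            layer = np.nanmean(layer, axis=0)
        valid = mask & np.isfinite(layer)
        if not valid.any():
            raise EmptyRegionError(
                f"region {region.name!r} has no unmasked cells in {year}-{m:02d}"
            )
        if cos_lat_weights:
            monthly.append(float(np.average(layer[valid], weights=w[valid])))
        else:
            monthly.append(float(layer[valid].mean()))
    return float(np.mean(monthly))


@dataclass
class CovariateSeries:
    """A yearly covariate (region + variable + month window)."""

    label: str
    values: pd.Series  # index: year (int) -> value
    standardized: bool = False

    def __post_init__(self) -> None:
        vals = pd.Series(self.values).astype(float)
        vals.index = vals.index.astype(int)
        self.values = vals.sort_index()

    @property
    def years(self) -> np.ndarray:
        return self.values.index.values

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"year": self.values.index, "value": self.values.values})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "CovariateSeries":
        df = pd.read_csv(path)
        return cls(label or str(path), pd.Series(df["value"].values, index=df["year"]))


def standardize(series: CovariateSeries) -> CovariateSeries:
    """Center to zero mean and scale to unit sample SD (ddof=1).

    Idempotent within floating tolerance; a constant series raises
    :class:`DegenerateCovariateError`.
    """
    x = series.values
    if x.size < 2 or x.nunique() < 2:
        raise DegenerateCovariateError(f"{series.label}: fewer than 2 distinct values")
    sd = x.std(ddof=1)
    if sd == 0 or not math.isfinite(sd):
        raise DegenerateCovariateError(f"{series.label}: zero variance")
    return replace(series, values=(x - x.mean()) / sd, standardized=True)


class CorrelationResult(NamedTuple):
    r: float
    p: float
    defined: bool


#: sentinel-style result for correlations undefined on constant input
UNDEFINED_CORRELATION = CorrelationResult(float("nan"), float("nan"), False)


def _as_year_series(x) -> pd.Series:
    if isinstance(x, CovariateSeries):
        return x.values
    return pd.Series(x).astype(float)


def series_correlation(a, b) -> CorrelationResult:
    """Pearson r between two year-indexed series with a two-sided t-test p.

    Series are aligned on common years. Constant input yields the undefined
    marker rather than a number.
    """
    sa, sb = _as_year_series(a), _as_year_series(b)
    df = pd.concat({"a": sa, "b": sb}, axis=1, join="inner").dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 paired years")
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        return UNDEFINED_CORRELATION
    r, p = stats.pearsonr(df["a"].values, df["b"].values)
    return CorrelationResult(float(r), float(p), True)
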