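"""Per-cell NDVI-abundance correlation maps and kernel-area selection.

Each fine NDVI cell's monthly series is correlated with the yearly spring
index across years; 1x1 degree squares containing more than ``min_cells``
significantly positive fine cells form the kernel area, which is then split
into northern/southern subregions at a boundary latitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import xarray as xr
from scipy import stats
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .errors import BoundaryError, ResolutionError
from .grids import GridField, RegionGeometry
from .indices import CollatedIndex


@dataclass
class CorrelationMap:
    """Per-cell Pearson r and two-sided p across years for one month."""

    month: int
    r: xr.DataArray  # (lat, lon)
    p: xr.DataArray
    mask: xr.DataArray  # True where the correlation is undefined
    n_years: int

    def to_netcdf(self, path) -> None:
        ds = xr.Dataset(
            {"r": self.r, "p": self.p, "undefined": self.mask.astype("int8")},
            attrs={"month": self.month, "n_years": self.n_years},
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "CorrelationMap":
        ds = xr.open_dataset(path).load()
        out = cls(
            int(ds.attrs["month"]),
            ds["r"],
            ds["p"],
            ds["undefined"].astype(bool),
            int(ds.attrs["n_years"]),
        )
        ds.close()
        return out


def cellwise_correlation(
    ndvi_stack: GridField, index: CollatedIndex, month: int
) -> CorrelationMap:
    """Correlate one month's NDVI with the yearly log index, cell by cell.

    Cells with constant NDVI (or missing years) are masked, never zero-filled.
    Requires at least 5 overlapping years.
    """
    if not 1 <= month <= 12:
        raise ValueError(f"invalid month {month}")
    years = [int(y) for y in index.years if y in set(ndvi_stack.years)]
    if len(years) < 5:
        raise ValueError(f"only {len(years)} overlapping years (need >= 5)")
    layers = np.stack(
        [ndvi_stack.sel_year_month(y, month).values for y in years], axis=0
    )
    yv = index.index.loc[years].to_numpy(dtype=float)
    n = len(years)

    finite = np.isfinite(layers).all(axis=0)
    xm = layers - np.nanmean(layers, axis=0, keepdims=True)
    sx = np.sqrt(np.nansum(xm**2, axis=0))
    ym = yv - yv.mean()
    sy = float(np.sqrt((ym**2).sum()))
    undefined = ~finite | (sx == 0) | (sy == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("tij,t->ij", np.where(np.isfinite(xm), xm, 0.0), ym) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    r[undefined] = np.nan
    p[undefined] = np.nan

    coords = {"lat": ndvi_stack.lats, "lon": ndvi_stack.lons}
    return CorrelationMap(
        month,
        xr.DataArray(r, coords=coords, dims=("lat", "lon"), name="r"),
        xr.DataArray(p, coords=coords, dims=("lat", "lon"), name="p"),
        xr.DataArray(undefined, coords=coords, dims=("lat", "lon"), name="undefined"),
        n_years=n,
    )


@dataclass
class KernelArea:
    """A set of 1x1 degree squares retained by the cell-count rule."""

    squares: list[tuple[float, float]]  # SW corners (lon0, lat0)
    counts: dict[tuple[float, float], int]
    square_deg: float = 1.0
    subregions: dict[str, list[tuple[float, float]]] | None = None

    @property
    def centers(self) -> list[tuple[float, float]]:
        h = self.square_deg / 2
        return [(x + h, y + h) for x, y in self.squares]

    def subregion_of(self, square: tuple[float, float]) -> str | None:
        if not self.subregions:
            return None
        for name, sqs in self.subregions.items():
            if square in sqs:
                return name
        return None

    def region_geometry(self, name: str = "kernel") -> RegionGeometry:
        geom = RegionGeometry.from_squares(name, self.squares, self.square_deg)
        if self.subregions:
            geom.subregions = {
                k: unary_union(
                    [box(x, y, x + self.square_deg, y + self.square_deg) for x, y in v]
                )
                for k, v in self.subregions.items()
                if v
            }
        return geom

    def to_geojson(self, path) -> None:
        feats = []
        for sq in self.squares:
            x, y = sq
            feats.append(
                {
                    "type": "Feature",
                    "properties": {
                        "lon0": x,
                        "lat0": y,
                        "significant_cells": self.counts.get(sq, 0),
                        "subregion": self.subregion_of(sq),
                    },
                    "geometry": mapping(box(x, y, x + self.square_deg, y + self.square_deg)),
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_geojson(cls, path) -> "KernelArea":
        with open(path) as fh:
            gj = json.load(fh)
        squares, counts, subs = [], {}, {}
        for feat in gj["features"]:
            props = feat["properties"]
            sq = (float(props["lon0"]), float(props["lat0"]))
            squares.append(sq)
            counts[sq] = int(props.get("significant_cells", 0))
            if props.get("subregion"):
                subs.setdefault(props["subregion"], []).append(sq)
        return cls(squares, counts, subregions=subs or None)


def select_kernel(
    cmap: CorrelationMap,
    alpha: float = 0.05,
    min_cells: int = 30,
    cell_deg: float = 0.08,
    square_deg: float = 1.0,
) -> KernelArea:
    """Retain squares with strictly more than ``min_cells`` significant cells.

    A fine cell counts when its correlation is positive with two-sided
    p < alpha; cells are assigned to the square containing their center, and
    edge squares holding fewer cells remain eligible under the same rule.
    """
    lats, lons = cmap.r["lat"].values, cmap.r["lon"].values
    for vals in (lats, lons):
        if len(vals) > 1:
            spacing = float(np.median(np.diff(vals)))
            if spacing > cell_deg * 1.25:
                raise ResolutionError(
                    f"grid spacing {spacing:.3f} deg coarser than cell size {cell_deg} deg"
                )
    sig = (cmap.r.values > 0) & (cmap.p.values < alpha) & ~cmap.mask.values
    lat_i, lon_i = np.nonzero(sig)
    sq_lon = np.floor(lons[lon_i] / square_deg) * square_deg
    sq_lat = np.floor(lats[lat_i] / square_deg) * square_deg
    counts: dict[tuple[float, float], int] = {}
    for x, y in zip(sq_lon, sq_lat):
        counts[(float(x), float(y))] = counts.get((float(x), float(y)), 0) + 1
    squares = sorted(sq for sq, c in counts.items() if c > min_cells)
    return KernelArea(squares, {sq: counts[sq] for sq in squares}, square_deg)


def split_subregions(kernel: KernelArea, boundary_lat: float = 15.0) -> KernelArea:
    """Partition kernel squares at a boundary latitude by square center.

    Squares with center latitude >= boundary are northern, the rest southern.
    The default 15 N approximates the Sahel/Sahara border.
    """
    if not kernel.squares:
        raise BoundaryError("kernel is empty")
    lat0s = [y for _, y in kernel.squares]
    lo, hi = min(lat0s), max(lat0s) + kernel.square_deg
    if not (lo <= boundary_lat <= hi):
        raise BoundaryError(
            f"boundary {boundary_lat} outside kernel latitude span [{lo}, {hi}]"
        )
    h = kernel.square_deg / 2
    northern = [sq for sq in kernel.squares if sq[1] + h >= boundary_lat]
    southern = [sq for sq in kernel.squares if sq[1] + h < boundary_lat]
    return replace(kernel, subregions={"northern": northern, "southern": southern})
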