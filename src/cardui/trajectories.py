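"""Wind-borne, self-powered, daytime butterfly trajectories over the Sahara.

Butterflies fly inside a daily local-solar window (07:00-18:00 by default)
for up to four consecutive days, adding a fixed self-powered air vector
(6 m/s toward north) to the interpolated wind at a fixed flight altitude,
roosting in place overnight. Any sampled temperature below the activity
threshold terminates the trajectory; leaving the atmosphere hull ends it as
a domain exit. Success means crossing the Sahara (reaching the crossing
latitude, 28 N by default) or, for southern launches, landing in the
northern subregion of the kernel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import Point

from .errors import LaunchError, PolarSingularityError
from .grids import GridField, RegionGeometry
from .kernels import KernelArea

R_EARTH = 6_371_000.0
M_PER_DEG = R_EARTH * math.pi / 180.0  # ~111,195 m per degree of latitude


@dataclass(frozen=True)
class FlightBehavior:
    """The six behavioral assumptions as parameters."""

    airspeed: float = 6.0  # m/s self-powered
    heading_deg: float = 0.0  # compass bearing; 0 = due north
    window: tuple[float, float] = (7.0, 18.0)  # local solar hours
    max_days: int = 4
    min_temp: float = 10.0  # degC activity threshold at flight altitude
    altitudes: tuple[float, ...] = (1000.0, 1500.0, 2000.0)  # m amsl
    timestep: float = 600.0  # s

    def __post_init__(self) -> None:
        if self.airspeed < 0:
            raise ValueError("airspeed must be >= 0")
        if not self.window[0] < self.window[1]:
            raise ValueError("window start must precede end")

    @property
    def window_hours(self) -> float:
        return self.window[1] - self.window[0]

    @property
    def max_flight_hours(self) -> float:
        return self.max_days * self.window_hours

    @property
    def steps_per_day(self) -> int:
        return int(round(self.window_hours * 3600.0 / self.timestep))


@dataclass
class SuccessCriteria:
    """Crossing latitude plus the northern-subregion geometry."""

    crossing_lat: float = 28.0
    northern_geometry: object | None = None  # shapely geometry

    @classmethod
    def from_kernel(cls, kernel: KernelArea, crossing_lat: float = 28.0) -> "SuccessCriteria":
        geom = None
        if kernel.subregions and kernel.subregions.get("northern"):
            geom = RegionGeometry.from_squares(
                "northern", kernel.subregions["northern"], kernel.square_deg
            ).geometry
        return cls(crossing_lat, geom)


class AtmosphereFields:
    """Multilinear interpolator over (time[, level], lat, lon) for u, v, T."""

    def __init__(self, u: GridField, v: GridField, t: GridField):
        self.t0 = u.times[0]
        axes = [self._seconds(u.times)]
        self.has_level = u.levels is not None
        if self.has_level:
            axes.append(u.levels.astype(float))
        axes += [u.lats.astype(float), u.lons.astype(float)]
        vals = np.stack(
            [u.data.values, v.data.values, t.data.values], axis=-1
        ).astype(float)
        self._interp = RegularGridInterpolator(
            axes, vals, bounds_error=False, fill_value=np.nan
        )

    def _seconds(self, times: pd.DatetimeIndex) -> np.ndarray:
        return ((times - times[0]) / pd.Timedelta(seconds=1)).to_numpy(dtype=float)

    def sample(self, time: pd.Timestamp, alt: float, lat: float, lon: float):
        """Return (u, v, T) or None when the query leaves the hull."""
        ts = (time - self.t0) / pd.Timedelta(seconds=1)
        pt = (ts, alt, lat, lon) if self.has_level else (ts, lat, lon)
        out = self._interp(np.asarray(pt)[None, :])[0]
        if not np.all(np.isfinite(out)):
            return None
        return float(out[0]), float(out[1]), float(out[2])


def local_solar_time(utc_time: pd.Timestamp, lon: float) -> pd.Timestamp:
    """Local solar time: UTC + lon/15 hours (lon in [-180, 180))."""
    if not -180.0 <= lon < 180.0:
        raise ValueError("lon must lie in [-180, 180)")
    return pd.Timestamp(utc_time) + pd.Timedelta(hours=lon / 15.0)


def interp_wind(
    fields: AtmosphereFields, lon: float, lat: float, alt: float, time: pd.Timestamp
):
    """Sample (u, v, T); None signals a domain exit (consumed by the runner)."""
    return fields.sample(pd.Timestamp(time), alt, lat, lon)


def step(
    position: tuple[float, float],
    wind: tuple[float, float],
    behavior: FlightBehavior,
    dt: float,
) -> tuple[float, float]:
    """Advance (lon, lat) by one spherical-earth Euler step.

    Ground velocity is the wind plus the self-powered air vector along the
    preferred heading; with the default due-north heading the ground velocity
    is (u, v + airspeed).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    lon, lat = position
    if abs(lat) >= 89.0:
        raise PolarSingularityError(f"latitude {lat} too close to the pole")
    theta = math.radians(behavior.heading_deg)
    ug = wind[0] + behavior.airspeed * math.sin(theta)
    vg = wind[1] + behavior.airspeed * math.cos(theta)
    dlat = vg * dt / M_PER_DEG
    dlon = ug * dt / (M_PER_DEG * math.cos(math.radians(lat)))
    return lon + dlon, lat + dlat


@dataclass
class Trajectory:
    """A timestamped position path with termination status and category."""

    launch_lon: float
    launch_lat: float
    launch_date: object
    altitude: float
    times: list[pd.Timestamp]
    lons: list[float]
    lats: list[float]
    samples: list[tuple[float, float, float]]
    termination: str  # completed | cold_terminated | domain_exit
    category: str | None = None  # crossed_sahara | reached_north | failed
    launch_subregion: str | None = None
    flight_seconds: float = 0.0

    @property
    def endpoint(self) -> tuple[float, float]:
        return self.lons[-1], self.lats[-1]

    @property
    def max_lat(self) -> float:
        return max(self.lats)

    def to_geojson_feature(self) -> dict:
        return {
            "type": "Feature",
            "properties": {
                "launch_date": str(self.launch_date),
                "altitude": self.altitude,
                "termination": self.termination,
                "category": self.category,
                "subregion": self.launch_subregion,
            },
            "geometry": {
                "type": "LineString",
                "coordinates": [[x, y] for x, y in zip(self.lons, self.lats)],
            },
        }


def classify(
    traj: Trajectory,
    criteria: SuccessCriteria,
    launch_subregion: str | None = None,
) -> str:
    """Crossed if max latitude reaches the crossing latitude; otherwise a
    southern launch ending inside the northern subregion reached north."""
    if traj.max_lat >= criteria.crossing_lat:
        return "crossed_sahara"
    if (
        launch_subregion == "southern"
        and criteria.northern_geometry is not None
        and shapely.intersects(criteria.northern_geometry, Point(*traj.endpoint))
    ):
        return "reached_north"
    return "failed"


def run_trajectory(
    launch: tuple[float, float],
    date,
    altitude: float,
    fields: AtmosphereFields,
    behavior: FlightBehavior = FlightBehavior(),
    criteria: SuccessCriteria | None = None,
    launch_subregion: str | None = None,
) -> Trajectory:
    """Integrate one multi-day daytime trajectory.

    Each day's flight starts at 07:00 local solar time at the roost longitude
    and lasts the full daily window unless the trajectory is terminated; the
    position is frozen overnight. A sampled temperature below ``min_temp``
    terminates the whole trajectory; leaving the hull is a domain exit. With
    crossing criteria supplied, integration stops at the first crossing.
    """
    lon, lat = float(launch[0]), float(launch[1])
    dt = behavior.timestep
    day0 = pd.Timestamp(date).normalize()
    times: list[pd.Timestamp] = []
    lons, lats, samples = [lon], [lat], []
    termination = "completed"
    flight_s = 0.0
    crossed = False

    first_step = True
    for day in range(behavior.max_days):
        # the day's window is fixed by the roost longitude at dawn
        t = (
            day0
            + pd.Timedelta(days=day)
            + pd.Timedelta(hours=behavior.window[0])
            - pd.Timedelta(hours=lon / 15.0)
        )
        if not times:
            times.append(t)
        for _ in range(behavior.steps_per_day):
            sampled = fields.sample(t, altitude, lat, lon)
            if sampled is None:
                if first_step:
                    raise LaunchError(
                        f"launch ({lon}, {lat}) at {t} outside the atmosphere hull"
                    )
                termination = "domain_exit"
                break
            first_step = False
            u, v, temp = sampled
            samples.append(sampled)
            if temp < behavior.min_temp:
                termination = "cold_terminated"
                break
            lon, lat = step((lon, lat), (u, v), behavior, dt)
            t = t + pd.Timedelta(seconds=dt)
            flight_s += dt
            times.append(t)
            lons.append(lon)
            lats.append(lat)
            if criteria is not None and lat >= criteria.crossing_lat:
                crossed = True
                break
        if termination != "completed" or crossed:
            break

    traj = Trajectory(
        launch_lon=float(launch[0]),
        launch_lat=float(launch[1]),
        launch_date=pd.Timestamp(date).date(),
        altitude=altitude,
        times=times,
        lons=lons,
        lats=lats,
        samples=samples,
        termination=termination,
        launch_subregion=launch_subregion,
        flight_seconds=flight_s,
    )
    if criteria is not None:
        traj.category = classify(traj, criteria, launch_subregion)
    return traj


def run_batch(
    kernel: KernelArea,
    dates: Sequence,
    fields: AtmosphereFields,
    behavior: FlightBehavior = FlightBehavior(),
    criteria: SuccessCriteria | None = None,
    altitudes: Sequence[float] | None = None,
) -> pd.DataFrame:
    """One trajectory per (kernel-square center, date, altitude).

    Returns a row per trajectory; per-trajectory failures are recorded with
    termination='error' and the batch continues.
    """
    if criteria is None:
        criteria = SuccessCriteria.from_kernel(kernel)
    alts = tuple(altitudes) if altitudes is not None else behavior.altitudes
    rows = []
    for sq, center in zip(kernel.squares, kernel.centers):
        subregion = kernel.subregion_of(sq)
        for date in dates:
            d = pd.Timestamp(date)
            for alt in alts:
                try:
                    traj = run_trajectory(
                        center, d, alt, fields, behavior, criteria, subregion
                    )
                    rows.append(
                        {
                            "lon0": center[0],
                            "lat0": center[1],
                            "subregion": subregion,
                            "date": d.date(),
                            "year": d.year,
                            "month": d.month,
                            "altitude": alt,
                            "termination": traj.termination,
                            "category": traj.category,
                            "end_lon": traj.endpoint[0],
                            "end_lat": traj.endpoint[1],
                            "flight_hours": traj.flight_seconds / 3600.0,
                        }
                    )
                except Exception as exc:  # noqa: BLE001 - batch isolates failures
                    rows.append(
                        {
                            "lon0": center[0],
                            "lat0": center[1],
                            "subregion": subregion,
                            "date": d.date(),
                            "year": d.year,
                            "month": d.month,
                            "altitude": alt,
                            "termination": "error",
                            "category": None,
                            "end_lon": np.nan,
                            "end_lat": np.nan,
                            "flight_hours": np.nan,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_batch(batch: pd.DataFrame) -> pd.DataFrame:
    """Counts per year/month/altitude/category."""
    if batch.empty:
        return pd.DataFrame(
            columns=["year", "month", "altitude", "category", "n"]
        )
    return (
        batch.groupby(["year", "month", "altitude", "category"], dropna=False)
        .size()
        .rename("n")
        .reset_index()
    )


def monthly_success_stats(
    batch: pd.DataFrame, success=("crossed_sahara", "reached_north")
) -> pd.DataFrame:
    """Monthly 'successful trajectory' counts with mean and range."""
    if batch.empty:
        return pd.DataFrame(columns=["month", "mean", "min", "max"])
    per_period = (
        batch.groupby(["year", "month"])
        .apply(lambda g: int(g["category"].isin(success).sum()), include_groups=False)
        .rename("n_success")
        .reset_index()
    )
    return (
        per_period.groupby("month")["n_success"]
        .agg(["mean", "min", "max"])
        .reset_index()
    )


def trajectories_to_geojson(trajs: Iterable[Trajectory], path) -> None:
    feats = [t.to_geojson_feature() for t in trajs]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def headwind_feasibility(
    airspeed: float, headwind: float, distance_km: float, hours_per_day: float
) -> float:
    """Days of nonstop flight-boundary-layer flight needed against a headwind.

    Ground speed is (airspeed - headwind) converted to km/h; returns days to
    0.1 d, or ``inf`` when the headwind is not beatable.
    """
    if distance_km <= 0 or hours_per_day <= 0:
        raise ValueError("distance and hours per day must be positive")
    if headwind < 0:
        raise ValueError("headwind must be >= 0")
    if airspeed <= headwind:
        return float("inf")
    kmh = (airspeed - headwind) * 3.6
    return round(distance_km / kmh / hours_per_day, 1)
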