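"""Synthetic study data with planted, recoverable structure.

Three generators emulate the study's data layers so every pipeline stage is
testable without downloads:

* hourly u/v/T wind fields over a West Africa-like box, with a "harmattan"
  scenario of prevailing cool northeasterlies interrupted by warm southerly
  burst days (the burst-day list is returned for oracle bookkeeping);
* monthly 1/12-degree NDVI grids whose planted kernel squares track a latent
  winter-greenness driver with a configured interannual correlation;
* overdispersed Pollard-walk transect counts with site/year random
  intercepts and region-specific (bimodal in the north) phenology curves.

``gen_study`` chains the layers: latent savanna greenness drives the spring
immigration index, which drives the Mediterranean summer generation, the
early-summer influx to NW Europe, and the late-summer generation, each link
with a configured effect size. Every generator returns its ground truth, and
identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridField, RegionGeometry
from .indices import DEFAULT_WINDOWS, SeasonWindow

NDVI_BASE = 0.30
NDVI_AMPLITUDE = 0.08


# ---------------------------------------------------------------------------
# wind / temperature fields


@dataclass
class WindScenarioConfig:
    """Scenario parameters for hourly u/v/T fields on a 1-degree grid."""

    scenario: str = "harmattan"  # uniform | solid_rotation | harmattan
    lon_range: tuple[float, float] = (-20.0, 20.0)
    lat_range: tuple[float, float] = (4.0, 36.0)
    spacing: float = 1.0
    levels: tuple[float, ...] = (500.0, 2500.0)  # m amsl, hull covers 1000-2000
    start: str = "2010-01-01"
    n_days: int = 31
    uniform_uv: tuple[float, float] = (0.0, 5.0)
    uniform_temp: float = 20.0
    rotation_omega: float = 2e-5  # 1/s, solid-body rotation about box center
    prevailing_uv: tuple[float, float] = (-4.0, -6.0)  # harmattan northeasterlies
    prevailing_temp: float = 8.0  # cool at flight altitude: grounds migrants
    burst_uv: tuple[float, float] = (2.0, 16.0)  # southerly disturbance
    burst_temp: float = 22.0
    burst_prob: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.burst_prob <= 1.0:
            raise ValueError("burst_prob must be in [0, 1]")


@dataclass
class WindBundle:
    u: GridField
    v: GridField
    t: GridField
    burst_days: list  # datetime.date, declared ground truth
    config: WindScenarioConfig


def gen_wind_fields(config: WindScenarioConfig, seed: int) -> WindBundle:
    """Generate hourly wind/temperature fields for one scenario.

    Harmattan burst days are drawn i.i.d. with ``burst_prob`` per day; each
    day's fields are constant over its 24 hourly stamps.
    """
    rng = np.random.default_rng(seed)
    lons = np.arange(config.lon_range[0], config.lon_range[1] + 1e-9, config.spacing)
    lats = np.arange(config.lat_range[0], config.lat_range[1] + 1e-9, config.spacing)
    times = pd.date_range(config.start, periods=config.n_days * 24, freq="h")
    nt, nz, ny, nx = len(times), len(config.levels), len(lats), len(lons)

    shape = (nt, nz, ny, nx)
    u = np.empty(shape)
    v = np.empty(shape)
    t = np.empty(shape)
    burst_days: list = []

    if config.scenario == "uniform":
        u[:] = config.uniform_uv[0]
        v[:] = config.uniform_uv[1]
        t[:] = config.uniform_temp
    elif config.scenario == "solid_rotation":
        lon2, lat2 = np.meshgrid(lons, lats)
        xc = (config.lon_range[0] + config.lon_range[1]) / 2
        yc = (config.lat_range[0] + config.lat_range[1]) / 2
        m_per_deg = 111_195.0
        u2 = -config.rotation_omega * (lat2 - yc) * m_per_deg
        v2 = config.rotation_omega * (lon2 - xc) * m_per_deg
        u[:] = u2[None, None]
        v[:] = v2[None, None]
        t[:] = config.uniform_temp
    elif config.scenario == "harmattan":
        is_burst = rng.random(config.n_days) < config.burst_prob
        days = pd.date_range(config.start, periods=config.n_days, freq="D")
        burst_days = [d.date() for d, b in zip(days, is_burst) if b]
        day_idx = np.repeat(np.arange(config.n_days), 24)
        bursts_hourly = is_burst[day_idx]
        u[:] = np.where(bursts_hourly, config.burst_uv[0], config.prevailing_uv[0])[
            :, None, None, None
        ]
        v[:] = np.where(bursts_hourly, config.burst_uv[1], config.prevailing_uv[1])[
            :, None, None, None
        ]
        t[:] = np.where(bursts_hourly, config.burst_temp, config.prevailing_temp)[
            :, None, None, None
        ]
    else:
        raise ValueError(f"unknown scenario {config.scenario!r}")

    coords = {"time": times, "level": list(config.levels), "lat": lats, "lon": lons}
    dims = ("time", "level", "lat", "lon")

    def fld(arr, name, units):
        return GridField(xr.DataArray(arr, coords=coords, dims=dims, name=name), units)

    return WindBundle(
        fld(u, "u", "m s-1"), fld(v, "v", "m s-1"), fld(t, "T", "degC"),
        burst_days, config,
    )


# ---------------------------------------------------------------------------
# NDVI grids


@dataclass
class NdviPlantConfig:
    """Planted-kernel NDVI generator parameters."""

    lon_range: tuple[float, float] = (-20.0, 20.0)
    lat_range: tuple[float, float] = (4.0, 36.0)
    resolution: float = 1.0 / 12.0
    years: tuple[int, int] = (1994, 2015)  # inclusive
    months: tuple[int, ...] = (1, 2)
    kernel_squares: tuple[tuple[float, float], ...] = ((-6.0, 13.0), (-5.0, 13.0), (-5.0, 14.0))
    effect_r: float = 0.8  # target correlation of planted cells with the latent driver
    square_deg: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 < self.effect_r < 1.0:
            raise ValueError("effect correlation must lie strictly inside (-1, 1)")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class NdviBundle:
    ndvi: GridField
    latent: pd.Series  # year -> latent greenness driver (ground truth)
    config: NdviPlantConfig


def gen_env_grids(config: NdviPlantConfig, seed: int) -> NdviBundle:
    """Monthly NDVI grids with a planted latent-driver correlation.

    Inside the planted squares each cell's standardized year series is
    ``r * latent + sqrt(1-r^2) * noise``; outside it is independent noise.
    NDVI values are an affine map of the standardized series, clipped to the
    valid [-0.3, 1] range.
    """
    rng = np.random.default_rng(seed)
    res = config.resolution
    lons = np.arange(config.lon_range[0] + res / 2, config.lon_range[1], res)
    lats = np.arange(config.lat_range[0] + res / 2, config.lat_range[1], res)
    years = config.year_list
    latent = pd.Series(rng.standard_normal(len(years)), index=years)

    region = RegionGeometry.from_squares("plant", config.kernel_squares, config.square_deg)
    planted = region.contains_mask(lons, lats)  # (lat, lon)

    r = config.effect_r
    ny, nx, nyr, nmo = len(lats), len(lons), len(years), len(config.months)
    z = rng.standard_normal((nyr, nmo, ny, nx))
    z[:, :, planted] = (
        r * latent.values[:, None, None]
        + np.sqrt(1 - r**2) * z[:, :, planted]
    )
    ndvi = np.clip(NDVI_BASE + NDVI_AMPLITUDE * z, -0.3, 1.0)

    times, frames = [], []
    for iy, year in enumerate(years):
        for im, month in enumerate(config.months):
            times.append(pd.Timestamp(year=year, month=month, day=1))
            frames.append(ndvi[iy, im])
    da = xr.DataArray(
        np.stack(frames),
        coords={"time": pd.DatetimeIndex(times), "lat": lats, "lon": lons},
        dims=("time", "lat", "lon"),
        name="ndvi",
    )
    return NdviBundle(GridField(da, units="1"), latent, config)


# ---------------------------------------------------------------------------
# transect counts


@dataclass
class PhenologyBump:
    peak_doy: float
    sd_days: float
    weight: float = 1.0


#: qualitative seasonal shapes: single spring/summer pulses in the
#: Mediterranean, a bimodal pattern in NW Europe with the larger August peak
DEFAULT_PHENOLOGY = {
    ("NE Spain", "spring"): (PhenologyBump(115, 18.0),),
    ("NE Spain", "summer"): (PhenologyBump(176, 15.0),),
    ("NW Europe", "early_summer"): (PhenologyBump(170, 14.0),),
    ("NW Europe", "late_summer"): (PhenologyBump(222, 16.0),),
}


@dataclass
class CountModelConfig:
    """Generator for one region x season transect count set."""

    region: str = "NE Spain"
    season: str = "spring"
    window: SeasonWindow | None = None
    years: tuple[int, int] = (1994, 2015)
    n_sites: int = 30
    beta0: float = 1.0
    betas: dict = field(default_factory=dict)  # covariate label -> effect
    length_effect: float = 0.3  # on standardized transect length
    site_sd: float = 0.3
    year_sd: float = 0.2
    nb_size: float | None = None  # None = Poisson; else gamma-Poisson size
    visit_interval_days: int = 7
    phenology: tuple[PhenologyBump, ...] | None = None

    def __post_init__(self) -> None:
        if self.site_sd < 0 or self.year_sd < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.window is None:
            self.window = next(
                w
                for w in DEFAULT_WINDOWS
                if w.region == self.region and w.season == self.season
            )
        if self.phenology is None:
            self.phenology = DEFAULT_PHENOLOGY.get(
                (self.region, self.season), (PhenologyBump(150, 20.0),)
            )

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


def _phenology_weight(doy: np.ndarray, bumps: Sequence[PhenologyBump]) -> np.ndarray:
    w = np.zeros_like(np.asarray(doy, dtype=float))
    for b in bumps:
        w = w + b.weight * np.exp(-0.5 * ((doy - b.peak_doy) / b.sd_days) ** 2)
    return np.clip(w, 0.02, None)


@dataclass
class CountBundle:
    visits: pd.DataFrame
    truth: dict
    config: CountModelConfig


def gen_transect_counts(
    config: CountModelConfig,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    year_effects: pd.Series | None = None,
) -> CountBundle:
    """Simulate Pollard-walk visits for one region x season.

    log-mean = beta0 + beta.x_year + length effect + site intercept + year
    intercept + log phenology weight; counts are Poisson, or gamma-mixed
    Poisson (negative binomial) when ``nb_size`` is set. ``year_effects``
    optionally fixes the year intercepts (e.g. to a planted migration chain
    stage) instead of drawing them N(0, year_sd).
    """
    rng = np.random.default_rng(seed)
    years = config.year_list
    w = config.window
    sites = [f"{config.region[:2].upper()}{i:03d}" for i in range(config.n_sites)]
    lengths = rng.uniform(1000.0, 5000.0, size=config.n_sites)
    std_len = (lengths - lengths.mean()) / lengths.std(ddof=1)
    site_eff = rng.normal(0.0, config.site_sd, size=config.n_sites)
    if year_effects is None:
        yr_eff = pd.Series(rng.normal(0.0, config.year_sd, len(years)), index=years)
    else:
        yr_eff = year_effects.reindex(years).astype(float)
        if yr_eff.isna().any():
            raise ValueError("year_effects must cover every generator year")

    cov_term = pd.Series(0.0, index=years)
    if covariates is not None:
        for label, beta in config.betas.items():
            cov_term = cov_term + beta * covariates[label].reindex(years)

    rows = []
    for year in years:
        start = pd.Timestamp(year=year, month=w.start[0], day=w.start[1])
        end = pd.Timestamp(year=year, month=w.end[0], day=w.end[1])
        dates = pd.date_range(start, end, freq=f"{config.visit_interval_days}D")
        doy = dates.dayofyear.to_numpy(dtype=float)
        phen = _phenology_weight(doy, config.phenology)
        phen = phen / phen.mean()
        for s in range(config.n_sites):
            log_mu = (
                config.beta0
                + float(cov_term.loc[year])
                + config.length_effect * std_len[s]
                + site_eff[s]
                + float(yr_eff.loc[year])
                + np.log(phen)
            )
            mu = np.exp(np.clip(log_mu, -20, 20))
            if config.nb_size is not None and config.nb_size > 0:
                mu = mu * rng.gamma(config.nb_size, 1.0 / config.nb_size, size=mu.shape)
            counts = rng.poisson(mu)
            for d, c in zip(dates, counts):
                rows.append(
                    {
                        "site_id": sites[s],
                        "date": d.date().isoformat(),
                        "count": int(c),
                        "transect_length_m": float(round(lengths[s], 1)),
                        "region": config.region,
                    }
                )
    visits = pd.DataFrame(rows)
    truth = {
        "betas": dict(config.betas),
        "beta0": config.beta0,
        "site_effects": dict(zip(sites, site_eff)),
        "year_effects": yr_eff,
        "length_effect": config.length_effect,
    }
    return CountBundle(visits, truth, config)


# ---------------------------------------------------------------------------
# full study bundle


@dataclass
class StudyConfig:
    """The chained study: greenness -> spring -> summer -> NW Europe."""

    years: tuple[int, int] = (1994, 2015)
    chain_effects: tuple[float, float, float, float] = (0.8, 0.8, 0.8, 0.8)
    n_sites_med: int = 30
    n_sites_nw: int = 40
    year_noise_sd: float = 0.15  # extra year-level noise within each count set
    nb_size: float | None = 8.0  # mild overdispersion by default
    ndvi: NdviPlantConfig = field(default_factory=NdviPlantConfig)
    wind: WindScenarioConfig = field(default_factory=WindScenarioConfig)

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class StudyBundle:
    ndvi: NdviBundle
    winds: WindBundle
    counts: dict[tuple[str, str], CountBundle]
    stages: pd.DataFrame  # year x {latent, spring, summer, nwe_early, nwe_late}
    truth: dict
    config: StudyConfig


_STAGE_SETS = [
    ("spring", "NE Spain", "spring", "n_sites_med"),
    ("summer", "NE Spain", "summer", "n_sites_med"),
    ("nwe_early", "NW Europe", "early_summer", "n_sites_nw"),
    ("nwe_late", "NW Europe", "late_summer", "n_sites_nw"),
]


def gen_study(config: StudyConfig, seed: int) -> StudyBundle:
    """Generate the full synthetic study with a planted effect chain.

    Each stage's standardized yearly abundance driver is ``c`` times the
    previous stage plus independent noise, starting from the latent savanna
    greenness; the same latent series is planted in the NDVI kernel squares.
    """
    rng = np.random.default_rng(seed)
    years = config.year_list
    stages = {"latent": rng.standard_normal(len(years))}
    prev = stages["latent"]
    for c, (key, *_rest) in zip(config.chain_effects, _STAGE_SETS):
        prev = c * prev + np.sqrt(1 - c**2) * rng.standard_normal(len(years))
        stages[key] = prev
    stage_df = pd.DataFrame(stages, index=years)

    ndvi_cfg = NdviPlantConfig(
        **{
            **config.ndvi.__dict__,
            "years": config.years,
        }
    )
    ndvi = gen_env_grids(ndvi_cfg, int(rng.integers(2**31 - 1)))
    # the NDVI plant tracks the same latent driver the chain starts from
    ndvi = _replant_latent(ndvi_cfg, ndvi, stage_df["latent"], rng)

    winds = gen_wind_fields(config.wind, int(rng.integers(2**31 - 1)))

    counts: dict[tuple[str, str], CountBundle] = {}
    for key, region, season, nsite_attr in _STAGE_SETS:
        cfg = CountModelConfig(
            region=region,
            season=season,
            years=config.years,
            n_sites=getattr(config, nsite_attr),
            year_sd=config.year_noise_sd,
            nb_size=config.nb_size,
        )
        yr_eff = pd.Series(stage_df[key].values, index=years) + rng.normal(
            0.0, config.year_noise_sd, len(years)
        )
        counts[(region, season)] = gen_transect_counts(
            cfg, seed=int(rng.integers(2**31 - 1)), year_effects=yr_eff
        )

    truth = {
        "chain_effects": tuple(config.chain_effects),
        "burst_days": winds.burst_days,
        "latent": pd.Series(stage_df["latent"].values, index=years),
    }
    return StudyBundle(ndvi, winds, counts, stage_df, truth, config)


def _replant_latent(
    cfg: NdviPlantConfig, bundle: NdviBundle, latent: pd.Series, rng: np.random.Generator
) -> NdviBundle:
    """Re-plant the NDVI kernel cells against an externally supplied latent."""
    res = cfg.resolution
    fld = bundle.ndvi
    region = RegionGeometry.from_squares("plant", cfg.kernel_squares, cfg.square_deg)
    planted = region.contains_mask(fld.lons, fld.lats)
    r = cfg.effect_r
    data = fld.data.values.copy()
    times = fld.times
    lat_vals = latent.reindex(times.year).to_numpy()
    noise = rng.standard_normal((len(times), int(planted.sum())))
    z = r * lat_vals[:, None] + np.sqrt(1 - r**2) * noise
    data[:, planted] = np.clip(NDVI_BASE + NDVI_AMPLITUDE * z, -0.3, 1.0)
    new = GridField(
        xr.DataArray(
            data,
            coords={"time": times, "lat": fld.lats, "lon": fld.lons},
            dims=("time", "lat", "lon"),
            name="ndvi",
        ),
        units="1",
    )
    return NdviBundle(new, latent, cfg)
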