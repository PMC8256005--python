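"""End-to-end pipeline: simulate -> index -> kernels -> models -> trajectories.

Stages communicate through files in the run directory (CSV, NetCDF, GeoJSON,
JSON), so partial runs resume from cached stage outputs. A run manifest
records the config hash, seeds, per-stage inputs/outputs and versions;
re-running with the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .errors import PipelineConfigError
from .grids import CovariateSeries, GridField, load_grid, regional_mean, standardize
from .indices import DEFAULT_WINDOWS, CollatedIndex, collated_index, split_seasons
from .kernels import KernelArea, cellwise_correlation, select_kernel, split_subregions
from .models import BatteryModel, ModelSpec, model_battery
from .synthetic import (
    NdviPlantConfig,
    StudyConfig,
    WindScenarioConfig,
    gen_study,
)
from .trajectories import (
    AtmosphereFields,
    FlightBehavior,
    SuccessCriteria,
    run_batch,
    summarize_batch,
)

log = logging.getLogger(__name__)

STAGES = ["simulate-data", "build-index", "map-kernels", "fit-models", "run-trajectories"]


DEFAULT_CONFIG = {
    "seed": 1,
    "simulate": {"years": [1994, 2015], "n_days_wind": 60},
    "index": {},
    "kernels": {"alpha": 0.05, "min_cells": 30, "boundary_lat": 14.0, "month": 1},
    "models": {"alpha": 0.05},
    "trajectories": {"altitudes": [1500.0], "max_launch_days": 20},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    if path is None:
        return dict(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def stage_entry(self, name: str) -> dict | None:
        for st in self.stages:
            if st["name"] == name:
                return st
        return None

    def record(self, name: str, inputs: list[str], outputs: list[str]) -> None:
        self.stages = [st for st in self.stages if st["name"] != name]
        self.stages.append(
            {
                "name": name,
                "inputs": inputs,
                "outputs": outputs,
                "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )

    @property
    def manifest_hash(self) -> str:
        """Hash over config, seed and stage outputs; timestamps excluded."""
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": [
                {"name": s["name"], "inputs": s["inputs"], "outputs": s["outputs"]}
                for s in sorted(self.stages, key=lambda s: s["name"])
            ],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self) | {"manifest_hash": self.manifest_hash}, fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["config_hash"], d["seed"], d.get("versions", {}), d.get("stages", []))


def _index_paths(out: Path) -> dict[tuple[str, str], Path]:
    return {
        (w.region, w.season): out / f"index_{w.region.replace(' ', '_')}_{w.season}.csv"
        for w in DEFAULT_WINDOWS
    }


def stage_simulate(config: dict, out: Path) -> tuple[list[str], list[str]]:
    sim = config["simulate"]
    study_cfg = StudyConfig(
        years=tuple(sim.get("years", (1994, 2015))),
        ndvi=NdviPlantConfig(
            years=tuple(sim.get("years", (1994, 2015))),
            **(sim.get("ndvi") or {}),
        ),
        wind=WindScenarioConfig(n_days=sim.get("n_days_wind", 60), **(sim.get("wind") or {})),
    )
    bundle = gen_study(study_cfg, int(config["seed"]))
    visits = pd.concat(
        [
            cb.visits.assign(season=season)
            for (region, season), cb in bundle.counts.items()
        ],
        ignore_index=True,
    )
    visits.to_csv(out / "visits.csv", index=False)
    bundle.ndvi.ndvi.to_netcdf(out / "ndvi.nc")
    ds = xr.Dataset(
        {
            "u": bundle.winds.u.data,
            "v": bundle.winds.v.data,
            "T": bundle.winds.t.data,
        }
    )
    ds.to_netcdf(out / "winds.nc", engine="scipy")
    truth = {
        "stages": {k: list(map(float, v)) for k, v in bundle.stages.items()},
        "years": [int(y) for y in bundle.stages.index],
        "burst_days": [str(d) for d in bundle.winds.burst_days],
        "planted_squares": [list(sq) for sq in bundle.config.ndvi.kernel_squares],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return [], ["visits.csv", "ndvi.nc", "winds.nc", "truth.json"]


def stage_index(config: dict, out: Path) -> tuple[list[str], list[str]]:
    vpath = out / "visits.csv"
    if not vpath.exists():
        raise PipelineConfigError("visits.csv missing; run simulate-data first")
    visits = pd.read_csv(vpath)
    per_season = split_seasons(visits, DEFAULT_WINDOWS)
    outputs = []
    for (region, season), sub in per_season.items():
        if sub.empty:
            continue
        idx = collated_index(sub, region, season)
        path = _index_paths(out)[(region, season)]
        idx.to_csv(path)
        outputs.append(path.name)
    return ["visits.csv"], outputs


def stage_kernels(config: dict, out: Path) -> tuple[list[str], list[str]]:
    kc = config["kernels"]
    ndvi = load_grid(out / "ndvi.nc", "ndvi")
    spring_path = _index_paths(out)[("NE Spain", "spring")]
    if not spring_path.exists():
        raise PipelineConfigError("spring index missing; run build-index first")
    spring = CollatedIndex.from_csv(spring_path, "NE Spain", "spring")
    cmap = cellwise_correlation(ndvi, spring, month=int(kc.get("month", 1)))
    cmap.to_netcdf(out / "correlation_map.nc")
    kernel = select_kernel(cmap, alpha=kc["alpha"], min_cells=kc["min_cells"])
    if kernel.squares:
        kernel = split_subregions(kernel, boundary_lat=kc["boundary_lat"])
    kernel.to_geojson(out / "kernel.geojson")
    return ["ndvi.nc", spring_path.name], ["correlation_map.nc", "kernel.geojson"]


def _covariates_from_outputs(out: Path) -> pd.DataFrame:
    """Kernel NDVI mean by year plus previous-stage collated indices."""
    ndvi = load_grid(out / "ndvi.nc", "ndvi")
    kernel = KernelArea.from_geojson(out / "kernel.geojson")
    cov = {}
    if kernel.squares:
        region = kernel.region_geometry()
        vals = {
            int(y): regional_mean(ndvi, region, months=[1], year=int(y))
            for y in ndvi.years
        }
        cov["kernel_ndvi_jan"] = standardize(
            CovariateSeries("kernel_ndvi_jan", pd.Series(vals))
        ).values
    for region, season, label in [
        ("NE Spain", "spring", "spring_index"),
        ("NE Spain", "summer", "summer_index"),
        ("NW Europe", "early_summer", "nwe_early_index"),
    ]:
        path = _index_paths(out)[(region, season)]
        if path.exists():
            idx = CollatedIndex.from_csv(path)
            cov[label] = standardize(CovariateSeries(label, idx.index)).values
    return pd.DataFrame(cov)


def stage_models(config: dict, out: Path) -> tuple[list[str], list[str]]:
    visits = pd.read_csv(out / "visits.csv")
    per_season = split_seasons(visits, DEFAULT_WINDOWS)
    visit_sets = {
        f"{region}/{season}": sub for (region, season), sub in per_season.items()
    }
    covariates = _covariates_from_outputs(out)
    battery = []
    if "kernel_ndvi_jan" in covariates:
        battery.append(
            BatteryModel(
                ModelSpec("model1_spring", "NE Spain/spring", ("kernel_ndvi_jan",)),
                stepwise=False,
            )
        )
    battery += [
        BatteryModel(
            ModelSpec("model4_summer", "NE Spain/summer", ("spring_index",)),
            stepwise=False,
            aic_group="summer",
        ),
        BatteryModel(
            ModelSpec("model5_nwe_early", "NW Europe/early_summer", ("summer_index",)),
            stepwise=False,
        ),
        BatteryModel(
            ModelSpec("model7_nwe_late", "NW Europe/late_summer", ("nwe_early_index",)),
            stepwise=False,
        ),
    ]
    result = model_battery(battery, visit_sets, covariates, alpha=config["models"]["alpha"])
    result.comparison.to_csv(out / "model_results.csv", index=False)
    with open(out / "model_edges.json", "w") as fh:
        json.dump(
            {
                "edges": [list(e) for e in result.edges],
                "errors": result.errors,
            },
            fh,
            indent=2,
        )
    return ["visits.csv", "kernel.geojson"], ["model_results.csv", "model_edges.json"]


def stage_trajectories(config: dict, out: Path) -> tuple[list[str], list[str]]:
    tc = config["trajectories"]
    winds_path = out / "winds.nc"
    if not winds_path.exists():
        raise PipelineConfigError("winds.nc missing; run simulate-data first")
    ds = xr.open_dataset(winds_path).load()
    fields = AtmosphereFields(
        GridField(ds["u"]), GridField(ds["v"]), GridField(ds["T"])
    )
    kernel = KernelArea.from_geojson(out / "kernel.geojson")
    if not kernel.squares:
        summarize_batch(pd.DataFrame()).to_csv(out / "trajectory_summary.csv", index=False)
        return ["winds.nc", "kernel.geojson"], ["trajectory_summary.csv"]
    behavior = FlightBehavior(altitudes=tuple(tc.get("altitudes", (1500.0,))))
    criteria = SuccessCriteria.from_kernel(kernel)
    times = pd.DatetimeIndex(ds["time"].values)
    all_days = pd.date_range(times[0].normalize(), times[-1].normalize(), freq="D")
    usable = all_days[: max(len(all_days) - behavior.max_days, 1)]
    dates = usable[: int(tc.get("max_launch_days", 20))]
    batch = run_batch(kernel, dates, fields, behavior, criteria)
    batch.to_csv(out / "trajectories.csv", index=False)
    summarize_batch(batch).to_csv(out / "trajectory_summary.csv", index=False)
    ds.close()
    return ["winds.nc", "kernel.geojson"], ["trajectories.csv", "trajectory_summary.csv"]


_STAGE_FUNCS = {
    "simulate-data": stage_simulate,
    "build-index": stage_index,
    "map-kernels": stage_kernels,
    "fit-models": stage_models,
    "run-trajectories": stage_trajectories,
}


def run_pipeline(
    config: dict, outdir, stages: list[str] | None = None, resume: bool = True
) -> RunManifest:
    """Execute the requested stages in order and write the run manifest.

    With ``resume``, a stage whose outputs all exist under an unchanged
    config+seed is skipped; deleting one stage's outputs regenerates that
    stage (and anything downstream that consumes them) on the next run.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    manifest_path = out / "manifest.json"
    if resume and manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        if manifest.config_hash != chash or manifest.seed != int(config["seed"]):
            manifest = RunManifest(chash, int(config["seed"]))
    else:
        manifest = RunManifest(chash, int(config["seed"]))
    manifest.versions = {"cardui": __version__, "numpy": np.__version__}

    for name in stages or STAGES:
        if name not in _STAGE_FUNCS:
            raise PipelineConfigError(f"unknown stage {name!r}")
        prev = manifest.stage_entry(name)
        if (
            resume
            and prev is not None
            and prev["outputs"]
            and all((out / f).exists() for f in prev["outputs"])
        ):
            log.info("stage %s: outputs cached, skipping", name)
            continue
        log.info("stage %s: running", name)
        try:
            inputs, outputs = _STAGE_FUNCS[name](config, out)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise PipelineConfigError(f"stage {name!r} failed: {exc}") from exc
        manifest.record(name, inputs, outputs)
        manifest.save(manifest_path)
    manifest.save(manifest_path)
    return manifest
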