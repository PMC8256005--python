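"""The GLMM model battery: specs, collinearity screen, stepwise reduction.

Each model regresses seasonal transect counts (aggregated to site x year) on
standardized yearly covariates, with transect length and days-recorded as
fixed-effect controls and Site_ID and Year (categorical) as crossed random
intercepts under a Poisson error structure.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CollinearityError, DegenerateFitError
from .glmm import fit_poisson_glmm

log = logging.getLogger(__name__)

CONTROLS = ("transect_length", "days_recorded")
COLLINEARITY_LIMIT = 0.7


def _interaction_label(a: str, b: str) -> str:
    return f"{a}:{b}"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one Poisson GLMM."""

    name: str
    response: str  # key naming the region/season count set
    covariates: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    controls: tuple[str, ...] = CONTROLS
    random_intercepts: tuple[str, ...] = ("site", "year")

    def terms(self) -> list[str]:
        return (
            list(self.covariates)
            + [_interaction_label(a, b) for a, b in self.interactions]
            + list(self.controls)
        )

    def droppable_terms(self) -> list[str]:
        """Non-control fixed terms eligible for stepwise deletion."""
        return list(self.covariates) + [
            _interaction_label(a, b) for a, b in self.interactions
        ]


@dataclass
class FitResult:
    """Per-term estimates plus variance components and AIC for one model."""

    spec: ModelSpec
    table: pd.DataFrame  # term, beta, se, z, p
    vc: dict[str, float]
    aic: float
    loglik: float
    converged: bool
    n_obs: int

    def p_of(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])

    def beta_of(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "beta"])

    def se_of(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])


def _covariate_frame(covariates) -> pd.DataFrame:
    """Accept a DataFrame (year x label) or a dict of CovariateSeries."""
    if isinstance(covariates, pd.DataFrame):
        df = covariates.copy()
    else:
        df = pd.DataFrame({k: v.values for k, v in covariates.items()})
    df.index = df.index.astype(int)
    return df.sort_index()


def screen_collinearity(covariates, limit: float = COLLINEARITY_LIMIT) -> list[tuple[str, str, float]]:
    """Flag covariate pairs whose pairwise Pearson |r| >= limit."""
    df = _covariate_frame(covariates)
    flagged = []
    for a, b in itertools.combinations(df.columns, 2):
        sub = df[[a, b]].dropna()
        if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            continue
        r = float(sub[a].corr(sub[b]))
        if abs(r) >= limit:
            flagged.append((a, b, r))
    return flagged


def aggregate_site_year(visits: pd.DataFrame) -> pd.DataFrame:
    """Collapse visits to site x year rows: seasonal count total, effort controls."""
    df = visits.copy()
    df["year"] = pd.to_datetime(df["date"]).dt.year
    return (
        df.groupby(["site_id", "year"], as_index=False)
        .agg(
            count=("count", "sum"),
            days_recorded=("count", "size"),
            transect_length=("transect_length_m", "mean"),
        )
        .sort_values(["site_id", "year"])
        .reset_index(drop=True)
    )


def _standardize_column(x: np.ndarray, label: str) -> np.ndarray | None:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        log.info("control %r is constant; dropped from design", label)
        return None
    return (x - x.mean()) / sd


def build_design(spec: ModelSpec, visits: pd.DataFrame, covariates):
    """Assemble y, X, term names and random-effect codes for one model."""
    cov = _covariate_frame(covariates)
    data = aggregate_site_year(visits)
    years = sorted(set(data["year"]) & set(cov.index))
    if len(years) < 3:
        raise DegenerateFitError("fewer than 3 overlapping years")
    data = data[data["year"].isin(years)].reset_index(drop=True)

    cols = {"intercept": np.ones(len(data))}
    for label in spec.covariates:
        if label not in cov.columns:
            raise KeyError(f"covariate {label!r} not supplied")
        cols[label] = cov.loc[data["year"], label].to_numpy(dtype=float)
    for a, b in spec.interactions:
        xa = cov.loc[data["year"], a].to_numpy(dtype=float)
        xb = cov.loc[data["year"], b].to_numpy(dtype=float)
        cols[_interaction_label(a, b)] = xa * xb
    for ctrl in spec.controls:
        if ctrl not in data.columns:
            raise KeyError(f"control {ctrl!r} not in aggregated visits")
        std = _standardize_column(data[ctrl].to_numpy(dtype=float), ctrl)
        if std is not None:
            cols[ctrl] = std

    names = list(cols)
    X = np.column_stack([cols[k] for k in names])
    y = data["count"].to_numpy(dtype=float)
    groups = {}
    if "site" in spec.random_intercepts:
        groups["site"] = pd.Categorical(data["site_id"]).codes
    if "year" in spec.random_intercepts:
        groups["year"] = pd.Categorical(data["year"]).codes
    return y, X, names, groups


def fit_glmm(
    spec: ModelSpec,
    visits: pd.DataFrame,
    covariates,
    *,
    allow_collinear: bool = False,
    reml: bool = True,
) -> FitResult:
    """Fit one spec'd Poisson GLMM and return per-term statistics and AIC."""
    if len(spec.covariates) >= 2 and not allow_collinear:
        flagged = screen_collinearity(_covariate_frame(covariates)[list(spec.covariates)])
        if flagged:
            raise CollinearityError(
                f"model {spec.name!r}: collinear covariate pairs {flagged}"
            )
    y, X, names, groups = build_design(spec, visits, covariates)
    res = fit_poisson_glmm(y, X, groups, names, reml=reml)
    table = pd.DataFrame(
        {"term": names, "beta": res.beta, "se": res.se, "z": res.z, "p": res.p}
    )
    return FitResult(
        spec=spec,
        table=table,
        vc=res.vc,
        aic=res.aic,
        loglik=res.loglik,
        converged=res.converged,
        n_obs=res.n_obs,
    )


@dataclass
class StepwiseResult:
    spec: ModelSpec
    fit: FitResult
    trail: list[tuple[str, float]]  # (dropped term, its p at removal)


def stepwise_minimum(
    spec: ModelSpec, visits: pd.DataFrame, covariates, alpha: float = 0.05
) -> StepwiseResult:
    """Iteratively delete the least-significant non-control term (p >= alpha).

    Interactions are removed before their main effects; a main effect is only
    droppable once no remaining interaction involves it. Ties break by label
    order. Controls and random intercepts are never dropped.
    """
    current = spec
    trail: list[tuple[str, float]] = []
    while True:
        fit = fit_glmm(current, visits, covariates)
        inter_labels = [_interaction_label(a, b) for a, b in current.interactions]
        in_interactions = {t for pair in current.interactions for t in pair}
        candidates = [t for t in inter_labels if fit.p_of(t) >= alpha]
        if not candidates:
            candidates = [
                t
                for t in current.covariates
                if t not in in_interactions and fit.p_of(t) >= alpha
            ]
        if not candidates:
            return StepwiseResult(current, fit, trail)
        worst = max(sorted(candidates), key=lambda t: (fit.p_of(t), ))
        trail.append((worst, fit.p_of(worst)))
        if worst in inter_labels:
            keep = tuple(
                pair
                for pair in current.interactions
                if _interaction_label(*pair) != worst
            )
            current = replace(current, interactions=keep)
        else:
            current = replace(
                current, covariates=tuple(c for c in current.covariates if c != worst)
            )


@dataclass
class BatteryModel:
    """One battery entry: a spec, whether to reduce it, and an AIC group."""

    spec: ModelSpec
    stepwise: bool = True
    aic_group: str | None = None


@dataclass
class BatteryResult:
    results: dict[str, FitResult]
    stepwise_trails: dict[str, list[tuple[str, float]]]
    errors: dict[str, str]
    comparison: pd.DataFrame  # model, term, beta, se, z, p, aic, delta_aic
    edges: list[tuple[str, str, str, str]]  # (model, term, sign, response)


def model_battery(
    battery: Sequence[BatteryModel],
    visit_sets: dict[str, pd.DataFrame],
    covariates,
    alpha: float = 0.05,
) -> BatteryResult:
    """Run every configured model; failures are isolated per model.

    Emits a comparison table in the shape (model, term, beta, se, z, p, aic)
    with delta-AIC within each AIC group, plus a term -> sign -> response edge
    list of significant non-control effects.
    """
    results: dict[str, FitResult] = {}
    trails: dict[str, list[tuple[str, float]]] = {}
    errors: dict[str, str] = {}
    for entry in battery:
        spec = entry.spec
        try:
            visits = visit_sets[spec.response]
            if entry.stepwise:
                sw = stepwise_minimum(spec, visits, covariates, alpha=alpha)
                results[spec.name] = sw.fit
                trails[spec.name] = sw.trail
            else:
                results[spec.name] = fit_glmm(spec, visits, covariates)
                trails[spec.name] = []
        except Exception as exc:  # noqa: BLE001 - battery isolates failures
            log.warning("model %s failed: %s", spec.name, exc)
            errors[spec.name] = f"{type(exc).__name__}: {exc}"

    rows = []
    group_aic: dict[str, float] = {}
    for entry in battery:
        name = entry.spec.name
        if name in results and entry.aic_group:
            group_aic[entry.aic_group] = min(
                group_aic.get(entry.aic_group, np.inf), results[name].aic
            )
    edges = []
    for entry in battery:
        name = entry.spec.name
        if name not in results:
            continue
        fit = results[name]
        delta = (
            fit.aic - group_aic[entry.aic_group] if entry.aic_group else np.nan
        )
        for _, row in fit.table.iterrows():
            rows.append(
                {
                    "model": name,
                    "term": row["term"],
                    "beta": row["beta"],
                    "se": row["se"],
                    "z": row["z"],
                    "p": row["p"],
                    "aic": fit.aic,
                    "delta_aic": delta,
                }
            )
            if (
                row["term"] in fit.spec.droppable_terms()
                and row["p"] < alpha
            ):
                sign = "+" if row["beta"] > 0 else "-"
                edges.append((name, row["term"], sign, fit.spec.response))
    comparison = pd.DataFrame(rows)
    return BatteryResult(results, trails, errors, comparison, edges)
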