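import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from cardui.errors import CollinearityError, DegenerateFitError
from cardui.glmm import fit_poisson_glmm
from cardui.models import (
    BatteryModel,
    ModelSpec,
    aggregate_site_year,
    fit_glmm,
    model_battery,
    screen_collinearity,
    stepwise_minimum,
)
from cardui.synthetic import CountModelConfig, gen_transect_counts


def _std(x):
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std(ddof=1)


def _covariates(seed=0, labels=("x",), years=range(1994, 2016)):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {lab: _std(rng.standard_normal(len(list(years)))) for lab in labels},
        index=list(years),
    )


class TestScreenCollinearity:
    def test_duplicate_covariate_flagged(self):
        cov = _covariates(labels=("a",))
        cov["b"] = cov["a"]
        flagged = screen_collinearity(cov)
        assert len(flagged) == 1 and flagged[0][2] == pytest.approx(1.0)

    def test_correlation_just_below_limit_not_flagged(self):
        # construct a pair with r = 0.69 exactly
        n = 200
        rng = np.random.default_rng(3)
        a = _std(rng.standard_normal(n))
        e = _std(rng.standard_normal(n))
        e = _std(e - np.dot(e, a) / np.dot(a, a) * a)  # orthogonalize
        target = 0.69
        b = target * a + np.sqrt(1 - target**2) * e
        cov = pd.DataFrame({"a": a, "b": b}, index=range(n))
        assert screen_collinearity(cov) == []
        b_hi = 0.71 * a + np.sqrt(1 - 0.71**2) * e
        cov_hi = pd.DataFrame({"a": a, "b": b_hi}, index=range(n))
        assert len(screen_collinearity(cov_hi)) == 1

    def test_independent_normals_usually_unflagged(self):
        hits = 0
        for s in range(50):
            cov = _covariates(seed=100 + s, labels=("a", "b"))
            hits += bool(screen_collinearity(cov))
        assert hits <= 5  # |r|>=0.7 at n=22 is rare but not impossible

    def test_fit_refuses_flagged_pair(self):
        cov = _covariates(labels=("a",))
        cov["b"] = cov["a"]
        cb = gen_transect_counts(CountModelConfig(), seed=1)
        with pytest.raises(CollinearityError):
            fit_glmm(ModelSpec("m", "r", ("a", "b")), cb.visits, cov)


class TestFitGlmm:
    def test_intercept_only_equal_exposure_recovers_log_mean(self):
        rng = np.random.default_rng(9)
        n_site, n_year = 10, 8
        y = rng.poisson(12.0, size=n_site * n_year).astype(float)
        X = np.ones((len(y), 1))
        groups = {
            "site": np.repeat(np.arange(n_site), n_year),
            "year": np.tile(np.arange(n_year), n_site),
        }
        res = fit_poisson_glmm(y, X, groups, ["intercept"])
        assert res.beta[0] == pytest.approx(np.log(y.mean()), abs=0.02)
        assert res.vc["site"] < 0.01 and res.vc["year"] < 0.01

    def test_z_equals_beta_over_se_identity(self):
        cov = _covariates(seed=4)
        cb = gen_transect_counts(CountModelConfig(betas={"x": 0.5}), covariates=cov, seed=4)
        fit = fit_glmm(ModelSpec("m", "r", ("x",)), cb.visits, cov)
        assert np.allclose(
            fit.table["z"], fit.table["beta"] / fit.table["se"], atol=1e-6
        )
        assert np.isfinite(fit.aic) and fit.converged

    def test_planted_effect_recovered_single_seed(self):
        cov = _covariates(seed=8)
        cb = gen_transect_counts(CountModelConfig(betas={"x": 0.5}), covariates=cov, seed=8)
        fit = fit_glmm(ModelSpec("m", "r", ("x",)), cb.visits, cov)
        assert abs(fit.beta_of("x") - 0.5) <= 2 * fit.se_of("x")

    def test_planted_interaction_sign_recovered(self):
        # wind x greenness style interaction
        cov = _covariates(seed=15, labels=("wind", "ndvi"))
        cov["wind:ndvi"] = cov["wind"] * cov["ndvi"]
        cfg = CountModelConfig(betas={"wind": 0.2, "ndvi": 0.3, "wind:ndvi": 0.6})
        cb = gen_transect_counts(cfg, covariates=cov, seed=15)
        spec = ModelSpec("m", "r", ("wind", "ndvi"), interactions=(("wind", "ndvi"),))
        fit = fit_glmm(spec, cb.visits, cov.drop(columns="wind:ndvi"))
        assert fit.beta_of("wind:ndvi") > 0
        assert fit.p_of("wind:ndvi") < 0.05

    def test_all_zero_counts_is_degenerate(self):
        cov = _covariates()
        visits = pd.DataFrame(
            {
                "site_id": ["a"] * 6,
                "date": [f"{y}-04-01" for y in range(1994, 2000)],
                "count": [0] * 6,
                "transect_length_m": [1000.0] * 6,
                "region": ["r"] * 6,
            }
        )
        with pytest.raises(DegenerateFitError):
            fit_glmm(ModelSpec("m", "r", ()), visits, cov)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
class TestAgainstLme4:
    def test_matches_glmer_laplace_fit(self, tmp_path):
        """Independent oracle: the same ML Laplace fit in lme4."""
        cov = _covariates(seed=21)
        cb = gen_transect_counts(CountModelConfig(betas={"x": 0.5}), covariates=cov, seed=21)
        fit = fit_glmm(ModelSpec("m", "r", ("x",)), cb.visits, cov, reml=False)

        agg = aggregate_site_year(cb.visits)
        agg["x"] = cov.loc[agg["year"], "x"].values
        tl = agg["transect_length"]
        agg["tlen"] = (tl - tl.mean()) / tl.std(ddof=1)
        csv = tmp_path / "d.csv"
        agg.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            f"""
            suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
            d <- read.csv("{csv}")
            m <- glmer(count ~ x + tlen + (1|site_id) + (1|year), data=d, family=poisson)
            s <- summary(m)$coefficients
            v <- as.data.frame(VarCorr(m))
            cat(toJSON(list(beta=unname(s[,1]), se=unname(s[,2]),
                            vc=v$vcov, aic=AIC(m)), digits=10))
            """
        )
        out = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True, check=True
        )
        oracle = json.loads(out.stdout)
        mine = fit.table.set_index("term")
        assert mine.loc["intercept", "beta"] == pytest.approx(oracle["beta"][0], abs=0.02)
        assert mine.loc["x", "beta"] == pytest.approx(oracle["beta"][1], abs=0.02)
        assert mine.loc["x", "se"] == pytest.approx(oracle["se"][1], rel=0.05)
        assert fit.aic == pytest.approx(oracle["aic"][0], abs=1.0)


class TestStepwise:
    def test_all_significant_spec_unchanged(self):
        cov = _covariates(seed=30, labels=("a", "b"))
        cfg = CountModelConfig(betas={"a": 0.6, "b": 0.6}, year_sd=0.05)
        cb = gen_transect_counts(cfg, covariates=cov, seed=30)
        spec = ModelSpec("m", "r", ("a", "b"))
        sw = stepwise_minimum(spec, cb.visits, cov)
        assert sw.spec == spec and sw.trail == []

    def test_null_covariate_dropped_and_refit_reproduces(self):
        cov = _covariates(seed=31, labels=("real", "null"))
        cfg = CountModelConfig(betas={"real": 0.8})
        cb = gen_transect_counts(cfg, covariates=cov, seed=31)
        sw = stepwise_minimum(ModelSpec("m", "r", ("real", "null")), cb.visits, cov)
        assert "null" not in sw.spec.covariates
        # refitting the minimal model from scratch reproduces the estimates
        refit = fit_glmm(sw.spec, cb.visits, cov)
        assert np.allclose(
            refit.table["beta"].values,
            sw.fit.table["beta"].values,
            atol=1e-6,
        )

    def test_interactions_removed_before_main_effects(self):
        cov = _covariates(seed=32, labels=("a", "b"))
        cfg = CountModelConfig(betas={"a": 0.8})
        cb = gen_transect_counts(cfg, covariates=cov, seed=32)
        spec = ModelSpec("m", "r", ("a", "b"), interactions=(("a", "b"),))
        sw = stepwise_minimum(spec, cb.visits, cov)
        if sw.trail and "b" in [t for t, _ in sw.trail]:
            dropped = [t for t, _ in sw.trail]
            assert dropped.index("a:b") < dropped.index("b")


class TestBattery:
    def test_failures_isolated(self):
        cov = _covariates(seed=40)
        cb = gen_transect_counts(CountModelConfig(betas={"x": 0.5}), covariates=cov, seed=40)
        battery = [
            BatteryModel(ModelSpec("good", "counts", ("x",)), stepwise=False),
            BatteryModel(ModelSpec("bad", "missing_key", ("x",)), stepwise=False),
        ]
        res = model_battery(battery, {"counts": cb.visits}, cov)
        assert "good" in res.results
        assert "bad" in res.errors and "bad" not in res.results
        assert ("good", "x", "+", "counts") in res.edges

    def test_delta_aic_within_group(self):
        cov = _covariates(seed=41, labels=("a", "b"))
        cb = gen_transect_counts(CountModelConfig(betas={"a": 0.5}), covariates=cov, seed=41)
        battery = [
            BatteryModel(ModelSpec("v1", "c", ("a",)), stepwise=False, aic_group="g"),
            BatteryModel(ModelSpec("v2", "c", ("b",)), stepwise=False, aic_group="g"),
        ]
        res = model_battery(battery, {"c": cb.visits}, cov)
        d = res.comparison.groupby("model")["delta_aic"].first()
        assert d.min() == pytest.approx(0.0)
        assert (d >= 0).all()
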