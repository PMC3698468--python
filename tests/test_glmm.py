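import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from phyloherbivory.glmm import (
    FitOptions,
    ModelData,
    ModelDataError,
    build_model_data,
    fit_laplace,
    marginal_loglik,
    predict_linear,
)
from phyloherbivory.survey import PlantObservation, PlotComposition, build_predictors

from conftest import FAST_OPTS
from oracles import agq_single_factor_loglik, irls_logistic


def _single_factor_data(y, n, groups, n_groups, X=None):
    n_obs = len(y)
    return ModelData(
        y=y,
        n=n,
        X=np.ones((n_obs, 1)) if X is None else X,
        colnames=("intercept",) if X is None else tuple(f"x{i}" for i in range(X.shape[1])),
        species_idx=np.asarray(groups),
        plot_idx=np.zeros(n_obs, dtype=int),
        species_levels=tuple(f"g{i}" for i in range(n_groups)),
        plot_levels=("p0",),
    )


def _random_dataset(rng, n_groups=6, per=4, sigma=0.8, beta=0.4):
    gi = np.repeat(np.arange(n_groups), per)
    n = rng.poisson(10, n_groups * per) + 1
    u = rng.normal(0, sigma, n_groups)
    y = rng.binomial(n, expit(beta + u[gi]))
    return y.astype(float), n.astype(float), gi


class TestBuildModelData:
    def _predictors(self):
        # five plots with generic predictor values so the five-column
        # design (intercept, date, sr, pd, sr*pd) has full rank
        comps = [
            PlotComposition("p1", {"A": 2, "B": 1}, date=0),
            PlotComposition("p2", {"A": 1, "B": 3, "C": 1}, date=3),
            PlotComposition("p3", {"A": 1, "B": 1, "C": 2, "D": 1}, date=5),
            PlotComposition("p4", {"A": 4}, date=7),
            PlotComposition("p5", {"A": 1, "D": 2}, date=11),
        ]
        return build_predictors(
            comps, {"p1": 0.4, "p2": 0.8, "p3": 0.3, "p4": 0.6, "p5": 0.9}
        )

    def test_levels_and_shapes(self):
        plants = [
            PlantObservation("p1", "A", 1, 5),
            PlantObservation("p1", "B", 2, 6),
            PlantObservation("p2", "A", 0, 4),
            PlantObservation("p2", "B", 4, 4),
            PlantObservation("p3", "A", 2, 9),
            PlantObservation("p4", "A", 3, 7),
            PlantObservation("p5", "B", 1, 3),
        ]
        data = build_model_data(plants, self._predictors())
        assert data.n_obs == 7
        assert data.n_species == 2
        assert data.n_plots == 5
        assert data.X.shape == (7, 5)
        # plot predictors broadcast to the plants of that plot
        np.testing.assert_allclose(data.X[0, 2], data.X[1, 2])

    def test_orphan_plot_is_keyed_error(self):
        plants = [PlantObservation("p9", "A", 1, 5)]
        with pytest.raises(ModelDataError, match="p9"):
            build_model_data(plants, self._predictors())

    def test_unknown_species_with_closed_levels(self):
        plants = [PlantObservation("p1", "Z", 1, 5)]
        with pytest.raises(ModelDataError, match="Z"):
            build_model_data(plants, self._predictors(), species_levels=("A", "B"))

    def test_study_shape(self, study):
        data = build_model_data(study.plants, study.predictors)
        assert data.n_plots == 38
        assert data.n_species == 27
        assert data.n_obs == len(study.plants)

    def test_drop_column_keeps_interaction(self, study):
        data = build_model_data(study.plants, study.predictors)
        reduced = data.drop_column("sr")
        assert reduced.colnames == ("intercept", "date", "pd", "sr_pd")


class TestGLMLimit:
    def test_pooled_intercept_half_damage(self):
        data = _single_factor_data([30.0], [60.0], [0], 1)
        fit = fit_laplace(data, fixed_sigma={"species": 0, "plot": 0, "obs": 0})
        assert fit.coef["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_irls_oracle(self):
        rng = np.random.default_rng(5)
        n_obs = 40
        X = np.column_stack([np.ones(n_obs), rng.normal(size=n_obs)])
        n = rng.poisson(8, n_obs) + 1
        y = rng.binomial(n, expit(0.3 + 0.7 * X[:, 1]))
        data = _single_factor_data(y.astype(float), n.astype(float), np.zeros(n_obs, int), 1, X=X)
        fit = fit_laplace(data, fixed_sigma={"species": 0, "plot": 0, "obs": 0})
        beta_ref, dev_ref = irls_logistic(y, n, X)
        np.testing.assert_allclose(fit.coef.to_numpy(), beta_ref, atol=1e-6)
        assert fit.deviance == pytest.approx(dev_ref, abs=1e-6)

    def test_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        n_obs = 60
        X = np.column_stack([np.ones(n_obs), rng.normal(size=n_obs)])
        n = rng.poisson(12, n_obs) + 1
        y = rng.binomial(n, expit(-0.2 + 0.5 * X[:, 1]))
        data = _single_factor_data(y.astype(float), n.astype(float), np.zeros(n_obs, int), 1, X=X)
        fit = fit_laplace(data, fixed_sigma={"species": 0, "plot": 0, "obs": 0})
        ref = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coef.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se.to_numpy(), ref.bse, rtol=1e-4)


class TestLaplaceAccuracy:
    def test_single_factor_loglik_close_to_quadrature(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            y, n, gi = _random_dataset(rng)
            data = _single_factor_data(y, n, gi, 6)
            beta = rng.normal(0, 0.5)
            sigma = rng.uniform(0.2, 1.5)
            lap = marginal_loglik(data, [beta], [sigma, 0.0, 0.0])
            agq = agq_single_factor_loglik(y, n, beta, sigma, gi)
            assert lap == pytest.approx(agq, abs=0.1)

    def test_matches_lme4_reference(self, tmp_path):
        # crossed species x plot design with an observation-level effect,
        # compared against glmer's fast Laplace variant (nAGQ=0), which
        # optimises the same profiled objective
        rng = np.random.default_rng(23)
        S, P, per = 8, 12, 2
        si = np.repeat(np.arange(S), P * per)
        pi = np.tile(np.repeat(np.arange(P), per), S)
        n_obs = len(si)
        x = rng.normal(size=P)[pi]
        n = rng.poisson(10, n_obs) + 1
        eta = 0.2 + 0.5 * x + rng.normal(0, 1.0, S)[si] + rng.normal(0, 0.4, P)[pi] \
            + rng.normal(0, 0.5, n_obs)
        y = rng.binomial(n, expit(eta))
        X = np.column_stack([np.ones(n_obs), x])
        data = ModelData(
            y=y, n=n, X=X, colnames=("intercept", "x"),
            species_idx=si, plot_idx=pi,
            species_levels=tuple(f"s{i}" for i in range(S)),
            plot_levels=tuple(f"p{i}" for i in range(P)),
        )
        fit = fit_laplace(data)

        df = pd.DataFrame({"y": y, "n": n, "x": x, "s": si, "p": pi, "o": np.arange(n_obs)})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            d <- read.csv("{csv}")
            suppressMessages(library(lme4))
            m <- glmer(cbind(y, n - y) ~ x + (1|s) + (1|p) + (1|o),
                       data=d, family=binomial, nAGQ=0)
            vc <- as.data.frame(VarCorr(m))
            cat(sprintf("%.10f\\n", c(fixef(m),
                vc$vcov[vc$grp=="s"], vc$vcov[vc$grp=="p"], vc$vcov[vc$grp=="o"],
                as.numeric(logLik(m)))))
            """
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        b0, b1, v_s, v_p, v_o, ll = map(float, out.stdout.split())
        assert fit.coef["intercept"] == pytest.approx(b0, abs=2e-3)
        assert fit.coef["x"] == pytest.approx(b1, abs=2e-3)
        assert fit.vc.species == pytest.approx(v_s, abs=5e-3)
        assert fit.vc.plot == pytest.approx(v_p, abs=5e-3)
        assert fit.vc.obs == pytest.approx(v_o, abs=5e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-2)


class TestFitProperties:
    def test_z_is_estimate_over_se(self, study_fit):
        fit, _ = study_fit
        np.testing.assert_array_equal(
            fit.zvalues.to_numpy(), (fit.coef / fit.se).to_numpy()
        )

    def test_conditional_modes_center_near_zero(self, study_fit):
        fit, _ = study_fit
        for factor in ("species", "plot"):
            sigma = fit.vc.as_dict()[factor] ** 0.5
            if sigma > 0:
                assert abs(fit.ranef[factor].mean()) < 0.05 * sigma

    def test_conditional_sds_positive(self, study_fit):
        fit, _ = study_fit
        for factor in ("species", "plot", "obs"):
            assert (fit.ranef_sd[factor] > 0).all()

    def test_outer_objective_trace_reaches_minimum(self, study_fit):
        fit, _ = study_fit
        assert -fit.loglik == pytest.approx(min(fit.trace), abs=1e-6)

    def test_shrinkage_toward_zero(self):
        # every conditional mode lies strictly between zero and the raw
        # group residual offset from a fixed-effects-only fit
        rng = np.random.default_rng(31)
        y, n, gi = _random_dataset(rng, n_groups=8, per=5, sigma=1.0)
        data = _single_factor_data(y, n, gi, 8)
        fit = fit_laplace(data, fixed_sigma={"plot": 0, "obs": 0})
        alpha0 = fit.coef["intercept"]
        for g in range(8):
            sel = gi == g
            rate = y[sel].sum() / n[sel].sum()
            if rate in (0.0, 1.0):
                continue  # offset undefined at the boundary
            offset = logit(rate) - alpha0
            mode = fit.ranef["species"].iloc[g]
            assert 0 < abs(mode) < abs(offset)
            assert np.sign(mode) == np.sign(offset)

    def test_boundary_sigma_reported_as_zero(self):
        # a factor with no real grouping signal collapses to the boundary
        rng = np.random.default_rng(41)
        n_obs = 80
        n = rng.poisson(20, n_obs) + 1
        y = rng.binomial(n, 0.5)
        data = _single_factor_data(y.astype(float), n.astype(float), np.arange(n_obs) % 4, 4)
        fit = fit_laplace(data, fixed_sigma={"plot": 0.0})
        for k, flagged in fit.boundary.items():
            if flagged:
                assert fit.vc.as_dict()[k] == 0.0
        assert any(fit.boundary.values())

    def test_separation_flagged(self):
        data = _single_factor_data(
            np.array([10.0, 12.0, 9.0]), np.array([10.0, 12.0, 9.0]), [0, 0, 0], 1
        )
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_laplace(data, fixed_sigma={"species": 0, "plot": 0, "obs": 0})
        assert fit.separation


class TestPredictLinear:
    def test_all_components_zero_gives_half(self, small_fit):
        fit, _ = small_fit
        zeroed = fit.coef * 0.0
        fit2 = type(fit)(**{**fit.__dict__, "coef": zeroed})
        eta = predict_linear(fit2, {"intercept": 1.0})
        assert expit(eta) == pytest.approx(0.5)

    def test_additivity_of_requested_components(self, small_fit):
        fit, data = small_fit
        plot = data.plot_levels[0]
        species = data.species_levels[0]
        base = predict_linear(fit, {"intercept": 1.0})
        both = predict_linear(fit, {"intercept": 1.0}, plots=[plot], species=[species])
        expected = base + fit.ranef["plot"][plot] + fit.ranef["species"][species]
        np.testing.assert_allclose(both, expected, atol=1e-12)

    def test_unknown_level_is_error_not_zero(self, small_fit):
        fit, _ = small_fit
        with pytest.raises(KeyError, match="nope"):
            predict_linear(fit, {"intercept": 1.0}, plots=["nope"])

    def test_unknown_fixed_column_is_error(self, small_fit):
        fit, _ = small_fit
        with pytest.raises(KeyError, match="bogus"):
            predict_linear(fit, {"bogus": 1.0})
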