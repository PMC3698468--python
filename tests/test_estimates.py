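import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import spearmanr

from phyloherbivory.estimates import (
    DamageEstimate,
    estimates_table,
    fitted_surface,
    plot_damage,
    species_damage,
)
from phyloherbivory.glmm import VarianceComponents, build_model_data, fit_laplace, predict_linear
from phyloherbivory.synthetic import SimulationConfig, simulate_study

from conftest import FAST_OPTS


def _with_zero_parameters(fit):
    zero_ranef = {k: v * 0.0 for k, v in fit.ranef.items()}
    return type(fit)(**{
        **fit.__dict__,
        "coef": fit.coef * 0.0,
        "ranef": zero_ranef,
    })


class TestDamageEstimates:
    def test_interval_brackets_estimate(self):
        with pytest.raises(ValueError, match="bracket"):
            DamageEstimate("p", 0.5, 0.6, 0.7)

    def test_estimate_strictly_inside_unit_interval(self):
        with pytest.raises(ValueError):
            DamageEstimate("p", 1.0, 0.9, 1.0)

    def test_zero_parameters_give_half_everywhere(self, small_study, small_fit):
        fit, _ = small_fit
        zeroed = _with_zero_parameters(fit)
        for est in plot_damage(zeroed, small_study.predictors):
            assert est.estimate == pytest.approx(0.5)
        for est in species_damage(zeroed):
            assert est.estimate == pytest.approx(0.5)

    def test_matches_predict_linear_exactly(self, study, study_fit):
        fit, _ = study_fit
        frame = study.predictors.frame
        for est in plot_damage(fit, study.predictors):
            row = frame.loc[est.entity]
            eta = predict_linear(
                fit,
                {
                    "intercept": 1.0,
                    "sr": row["sr_c"],
                    "pd": row["pd_c"],
                    "sr_pd": row["sr_pd_c"],
                },
                plots=[est.entity],
            )
            assert est.estimate == expit(eta[0])
        for est in species_damage(fit):
            eta = predict_linear(fit, {"intercept": 1.0}, species=[est.entity])
            assert est.estimate == expit(eta[0])

    def test_estimates_strictly_inside_unit_interval_on_study(self, study, study_fit):
        fit, _ = study_fit
        for est in plot_damage(fit, study.predictors) + species_damage(fit):
            assert 0.0 < est.lower <= est.estimate <= est.upper < 1.0

    def test_increasing_a_plot_mode_increases_its_estimate(self, small_study, small_fit):
        fit, _ = small_fit
        plot = fit.ranef["plot"].index[0]
        bumped_ranef = {k: v.copy() for k, v in fit.ranef.items()}
        bumped_ranef["plot"][plot] += 0.7
        bumped = type(fit)(**{**fit.__dict__, "ranef": bumped_ranef})
        before = {e.entity: e.estimate for e in plot_damage(fit, small_study.predictors)}
        after = {e.entity: e.estimate for e in plot_damage(bumped, small_study.predictors)}
        assert after[plot] > before[plot]
        others = [p for p in before if p != plot]
        for p in others:
            assert after[p] == pytest.approx(before[p])

    def test_identical_species_get_identical_estimates(self):
        # two species with exactly the same records are exchangeable
        from phyloherbivory.survey import PlantObservation, PlotComposition, build_predictors

        comps = [
            PlotComposition("p1", {"A": 2, "B": 2, "C": 1}, date=0),
            PlotComposition("p2", {"A": 1, "B": 1, "C": 3}, date=2),
            PlotComposition("p3", {"A": 1, "B": 1}, date=4),
            PlotComposition("p4", {"A": 2, "C": 2}, date=5),
            PlotComposition("p5", {"B": 3, "C": 1}, date=7),
        ]
        predictors = build_predictors(
            comps, {"p1": 0.5, "p2": 0.7, "p3": 0.2, "p4": 0.9, "p5": 0.4}
        )
        plants = []
        for plot, damaged in (("p1", 3), ("p2", 7), ("p3", 5), ("p4", 2), ("p5", 8)):
            for sp in ("A", "B"):
                plants.append(PlantObservation(plot, sp, damaged, 10))
                plants.append(PlantObservation(plot, sp, damaged + 1, 12))
        data = build_model_data(plants, predictors)
        fit = fit_laplace(data, FAST_OPTS)
        est = {e.entity: e.estimate for e in species_damage(fit)}
        assert est["A"] == pytest.approx(est["B"], abs=1e-8)

    def test_species_range_spans_defended_to_palatable(self, study_fit):
        # with a species variance near the study's 2.4, estimated species
        # damage spans a low-to-high range
        fit, _ = study_fit
        values = [e.estimate for e in species_damage(fit)]
        assert min(values) < 0.25
        assert max(values) > 0.75

    def test_plot_ranking_recovers_true_plot_signal(self):
        config = SimulationConfig(sigma2_plot=1.0, seed=6)
        study = simulate_study(config)
        data = build_model_data(study.plants, study.predictors)
        fit = fit_laplace(data, FAST_OPTS)
        frame = study.predictors.frame
        b = config.betas()
        true_eta = {
            plot: (
                b["sr"] * frame.loc[plot, "sr_c"]
                + b["pd"] * frame.loc[plot, "pd_c"]
                + b["sr_pd"] * frame.loc[plot, "sr_pd_c"]
                + study.truth.plot_effects[plot]
            )
            for plot in frame.index
        }
        est = {e.entity: e.estimate for e in plot_damage(fit, study.predictors)}
        plots = sorted(est)
        rho = spearmanr([true_eta[p] for p in plots], [est[p] for p in plots]).statistic
        assert rho > 0.8


class TestFittedSurface:
    def test_zero_interaction_gives_parallel_logit_lines(self, study, study_fit):
        fit, _ = study_fit
        coef = fit.coef.copy()
        coef["sr_pd"] = 0.0
        flat = type(fit)(**{**fit.__dict__, "coef": coef})
        surface = fitted_surface(flat, study.predictors, sr_values=(3, 17))
        wide = surface.pivot(index="pd", columns="sr", values="logit")
        gaps = wide[17] - wide[3]
        assert np.ptp(gaps.to_numpy()) < 1e-10

    def test_surface_curvature_sign_matches_interaction(self, study, study_fit):
        fit, _ = study_fit
        surface = fitted_surface(fit, study.predictors, sr_values=(3, 6, 12, 17))
        wide = surface.pivot(index="pd", columns="sr", values="logit")
        slopes = (wide[17] - wide[3]) / (17 - 3)  # d logit / d SR at each PD
        d2 = np.diff(slopes.to_numpy()) / np.diff(wide.index.to_numpy())
        assert np.all(np.sign(d2) == np.sign(fit.coef["sr_pd"]))

    def test_default_sr_lines_span_observed_richness(self, study, study_fit):
        fit, _ = study_fit
        surface = fitted_surface(fit, study.predictors)
        assert sorted(surface["sr"].unique()) == [3.0, 6.0, 12.0, 17.0]
        assert surface["fitted_p"].between(0, 1).all()

    def test_grid_outside_hull_warns(self, study, study_fit):
        fit, _ = study_fit
        with pytest.warns(UserWarning, match="hull"):
            fitted_surface(fit, study.predictors, sr_values=(3, 40))

    def test_png_rendering_smoke(self, tmp_path, small_study, small_fit):
        from phyloherbivory.estimates import render_damage_png, render_surface_png

        fit, _ = small_fit
        surface = fitted_surface(fit, small_study.predictors, sr_values=(3, 5, 7))
        render_surface_png(surface, tmp_path / "surface.png")
        render_damage_png(species_damage(fit), tmp_path / "species.png")
        assert (tmp_path / "surface.png").stat().st_size > 0
        assert (tmp_path / "species.png").stat().st_size > 0

    def test_estimates_table_shape(self, small_study, small_fit):
        fit, _ = small_fit
        table = estimates_table(plot_damage(fit, small_study.predictors))
        assert list(table.columns) == ["entity", "estimate", "lower", "upper"]
        # one row per plot that contributed plants to the fit
        assert len(table) == len(fit.ranef["plot"])
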