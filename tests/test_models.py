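"""Gradient models: recovery against oracles, criteria, predictions."""

import numpy as np
import pandas as pd
import pytest

import arviz as az

from lakediv.models import (ModelSpec, ModelError, ci_sign, default_battery,
                            fit_hierarchical, fit_mixture,
                            information_criteria, predict_curves,
                            run_model_battery, waic_from_loglik)
from lakediv.zoning import orthogonal_poly

FAST = dict(chains=2, warmup=300, draws=350)


def poisson_world(seed=0, n=500, beta1=-0.5, group_sd=0.0, slope_sd=0.0, G=6):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 3000, n)
    g = rng.integers(0, G, n)
    basis = orthogonal_poly(x)
    p1 = basis.poly1 * np.sqrt(n)
    eta = (2.0 + rng.normal(0, group_sd, G)[g]
           + (beta1 + rng.normal(0, slope_sd, G)[g]) * p1)
    y = rng.poisson(np.exp(eta))
    return pd.DataFrame({"richness": y, "elevation": x, "zone": g}), basis


@pytest.fixture(scope="module")
def poisson_fit():
    data, _ = poisson_world(seed=1)
    spec = ModelSpec(response="richness", predictor="elevation",
                     family="poisson", grouping="zone", seed=1, **FAST)
    return fit_hierarchical(spec, data), data


class TestHierarchicalFit:
    def test_gaussian_intercept_only_sanity(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame({"y": rng.normal(3.0, 1.0, 200),
                             "x": rng.uniform(0, 1, 200),
                             "g": rng.integers(0, 4, 200)})
        spec = ModelSpec(response="y", predictor="x", family="gaussian",
                         grouping="g", seed=2, **FAST)
        fit = fit_hierarchical(spec, data)
        mu = fit.summary.loc["intercept"]
        sd = (mu["q97.5"] - mu["q2.5"]) / 4
        assert abs(mu["mean"] - data["y"].mean()) < 3 * sd

    def test_poisson_matches_ml_oracle(self, poisson_fit):
        import statsmodels.api as sm
        fit, data = poisson_fit
        n = len(data)
        basis = orthogonal_poly(data["elevation"].to_numpy())
        X = np.column_stack([np.ones(n), basis.poly1 * np.sqrt(n),
                             basis.poly2 * np.sqrt(n)])
        ml = sm.GLM(data["richness"], X,
                    family=sm.families.Poisson()).fit()
        assert abs(fit.summary.loc["beta1", "mean"] - ml.params[1]) < 0.1
        assert fit.summary.loc["beta1", "q2.5"] < -0.5 < fit.summary.loc["beta1", "q97.5"]

    def test_random_slope_sd_recovered(self):
        data, _ = poisson_world(seed=3, n=600, group_sd=0.3, slope_sd=0.3, G=6)
        spec = ModelSpec(response="richness", predictor="elevation",
                         family="gaussian", grouping="zone", seed=3, **FAST)
        # model the log response as gaussian to isolate the slope-sd question
        data["richness"] = np.log1p(data["richness"])
        fit = fit_hierarchical(spec, data)
        assert 0.1 < fit.summary.loc["tau_poly1", "median"] < 0.6

    def test_single_group_level_rejected(self):
        data, _ = poisson_world(seed=4, n=100)
        data["zone"] = 0
        spec = ModelSpec(response="richness", predictor="elevation",
                         family="poisson", grouping="zone", seed=4, **FAST)
        with pytest.raises(ModelError, match="single level"):
            fit_hierarchical(spec, data)

    def test_nonfinite_response_rejected(self):
        data, _ = poisson_world(seed=5, n=100)
        data.loc[0, "richness"] = np.inf
        spec = ModelSpec(response="richness", predictor="elevation",
                         family="gaussian", grouping="zone", seed=5, **FAST)
        with pytest.raises(ModelError, match="non-finite"):
            fit_hierarchical(spec, data)

    def test_scale_equivariance_of_standardized_design(self):
        """Doubling the raw predictor changes nothing downstream."""
        data, _ = poisson_world(seed=6, n=300)
        spec = ModelSpec(response="richness", predictor="elevation",
                         family="poisson", grouping="zone", seed=6, **FAST)
        fit_a = fit_hierarchical(spec, data)
        doubled = data.assign(elevation=2.0 * data["elevation"])
        fit_b = fit_hierarchical(spec, doubled)
        for p in ("beta1", "beta2"):
            assert fit_a.summary.loc[p, "mean"] == pytest.approx(
                fit_b.summary.loc[p, "mean"], abs=1e-9)

    def test_negbin_handles_overdispersed_counts(self):
        rng = np.random.default_rng(7)
        n = 400
        x = rng.uniform(0, 100, n)
        mu = np.exp(2.0)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu), n)
        data = pd.DataFrame({"y": y, "x": x, "g": rng.integers(0, 4, n)})
        spec = ModelSpec(response="y", predictor="x", family="negbin",
                         grouping="g", seed=7, **FAST)
        fit = fit_hierarchical(spec, data)
        assert 0.8 < fit.summary.loc["phi", "median"] < 5.0


class TestMixture:
    def test_two_component_recovery(self):
        rng = np.random.default_rng(8)
        y = np.where(rng.random(800) < 0.5,
                     rng.normal(-1, 0.4, 800), rng.normal(1, 0.4, 800))
        data = pd.DataFrame({"y": y, "x": rng.uniform(0, 5, 800)})
        spec = ModelSpec(response="y", predictor="x", family="mixture",
                         random_effects=False, seed=8, **FAST)
        fit = fit_mixture(spec, data)
        assert fit.summary.loc["mu1_intercept", "median"] == pytest.approx(-1, abs=0.2)
        assert fit.summary.loc["mu2_intercept", "median"] == pytest.approx(1, abs=0.2)
        assert fit.summary.loc["mixing", "median"] == pytest.approx(0.5, abs=0.1)

    def test_ordered_intercepts_in_every_draw(self):
        rng = np.random.default_rng(9)
        y = np.concatenate([rng.normal(0, 1, 200), rng.normal(3, 1, 200)])
        data = pd.DataFrame({"y": y, "x": rng.uniform(0, 5, 400)})
        spec = ModelSpec(response="y", predictor="x", family="mixture",
                         random_effects=False, seed=9, **FAST)
        fit = fit_mixture(spec, data)
        assert (fit.draws["mu1_intercept"] < fit.draws["mu2_intercept"]).all()
        assert fit.diagnostics["component_crossing_rate"] == 0.0

    def test_single_component_data_degenerates(self):
        """Unimodal data collapse the mixture: one component absorbs the
        weight, or the two components coincide (mixing then unidentified)."""
        rng = np.random.default_rng(10)
        data = pd.DataFrame({"y": rng.normal(0.5, 1.0, 500),
                             "x": rng.uniform(0, 5, 500)})
        spec = ModelSpec(response="y", predictor="x", family="mixture",
                         random_effects=False, seed=10, **FAST)
        fit = fit_mixture(spec, data)
        w = fit.summary.loc["mixing", "median"]
        gap = (fit.summary.loc["mu2_intercept", "median"]
               - fit.summary.loc["mu1_intercept", "median"])
        sigma = fit.summary.loc["sigma", "median"]
        assert (w < 0.25 or w > 0.75) or gap < 0.5 * sigma


class TestCiSign:
    def test_constant_positive(self, poisson_fit):
        fit, _ = poisson_fit
        fake = dict(fit.draws)
        fake["const"] = np.ones((2, 10))
        fit2 = fit.__class__(spec=fit.spec, param_names=list(fake),
                             draws=fake, summary=fit.summary,
                             diagnostics=fit.diagnostics, design=fit.design)
        assert ci_sign(fit2, "const") == "positive"

    def test_symmetric_uncertain_and_normal_positive(self, poisson_fit):
        fit, _ = poisson_fit
        rng = np.random.default_rng(11)
        fake = dict(fit.draws)
        fake["sym"] = rng.normal(0, 1, (2, 2000))
        fake["pos"] = rng.normal(0.5, 0.1, (2, 2000))
        fit2 = fit.__class__(spec=fit.spec, param_names=list(fake),
                             draws=fake, summary=fit.summary,
                             diagnostics=fit.diagnostics, design=fit.design)
        assert ci_sign(fit2, "sym") == "uncertain"
        assert ci_sign(fit2, "pos") == "positive"

    def test_unknown_parameter_raises(self, poisson_fit):
        fit, _ = poisson_fit
        with pytest.raises(KeyError):
            ci_sign(fit, "nonexistent")


class TestInformationCriteria:
    def test_self_comparison_zero_delta(self, poisson_fit):
        fit, _ = poisson_fit
        comp = information_criteria({"a": fit, "b": fit})
        assert comp.table["delta_waic"].max() == pytest.approx(0.0, abs=1e-9)
        assert comp.table["delta_looic"].max() == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_data_prefers_poly2_model(self):
        rng = np.random.default_rng(12)
        n = 500
        x = rng.uniform(-2, 2, n)
        basis = orthogonal_poly(x)
        y = 1.0 + 2.5 * basis.poly2 * np.sqrt(n) + rng.normal(0, 1, n)
        data = pd.DataFrame({"y": y, "x": x, "g": rng.integers(0, 4, n)})
        full = fit_hierarchical(ModelSpec(
            response="y", predictor="x", family="gaussian", grouping="g",
            seed=12, **FAST), data)
        flat = fit_hierarchical(ModelSpec(
            response="y", predictor="x", family="gaussian", grouping=None,
            random_effects=False, include_poly2=False, seed=13, **FAST), data)
        comp = information_criteria({"quadratic": full, "linear": flat})
        assert comp.table.loc["linear", "delta_waic"] > 10
        assert comp.table.loc["linear", "delta_looic"] > 10

    def test_waic_matches_independent_recomputation(self, poisson_fit):
        fit, _ = poisson_fit
        ll = fit.log_likelihood_matrix()
        waic, _ = waic_from_loglik(ll)
        flat = ll.reshape(-1, ll.shape[-1])
        s = flat.shape[0]
        lppd = np.sum(np.log(np.exp(flat - flat.max(0)).mean(0)) + flat.max(0))
        p = flat.var(axis=0, ddof=1).sum()
        assert waic == pytest.approx(-2 * (lppd - p), abs=1e-6)
        # cross-check against arviz; small gap expected from the variance
        # convention in p_waic (sample vs population variance over draws)
        az_waic = az.waic(fit.to_inference_data(), scale="deviance")
        s = flat.shape[0]
        convention_gap = 2 * p / (s - 1)
        assert abs(waic - float(az_waic.elpd_waic)) <= convention_gap + 1e-6


class TestPredictCurves:
    def test_identity_link_at_mean_is_intercept(self):
        rng = np.random.default_rng(14)
        data = pd.DataFrame({"y": rng.normal(2.0, 0.3, 300),
                             "x": rng.uniform(0, 10, 300),
                             "g": rng.integers(0, 4, 300)})
        spec = ModelSpec(response="y", predictor="x", family="gaussian",
                         grouping="g", seed=14, **FAST)
        fit = fit_hierarchical(spec, data)
        curves = predict_curves(fit, [data["x"].mean()], level="population")
        assert curves["median"].iloc[0] == pytest.approx(
            fit.summary.loc["intercept", "median"], abs=0.05)

    def test_flat_poisson_mean_seven(self):
        rng = np.random.default_rng(15)
        data = pd.DataFrame({"y": rng.poisson(7.0, 500),
                             "x": rng.uniform(0, 10, 500),
                             "g": rng.integers(0, 5, 500)})
        spec = ModelSpec(response="y", predictor="x", family="poisson",
                         grouping="g", seed=15, **FAST)
        fit = fit_hierarchical(spec, data)
        curves = predict_curves(fit, np.linspace(1, 9, 5), level="population")
        assert curves["median"].to_numpy() == pytest.approx(7.0, abs=0.7)

    def test_zero_group_variance_group_curves_match_population(self):
        rng = np.random.default_rng(16)
        x = rng.uniform(0, 10, 400)
        data = pd.DataFrame({"y": 1.0 + 0.5 * (x - x.mean()) / x.std()
                             + rng.normal(0, 0.2, 400),
                             "x": x, "g": rng.integers(0, 4, 400)})
        spec = ModelSpec(response="y", predictor="x", family="gaussian",
                         grouping="g", seed=16, **FAST)
        fit = fit_hierarchical(spec, data)
        grid = np.linspace(2, 8, 4)
        pop = predict_curves(fit, grid, level="population")
        grp = predict_curves(fit, grid, level="group")
        for g, block in grp.groupby("group"):
            assert block["median"].to_numpy() == pytest.approx(
                pop["median"].to_numpy(), abs=0.15)


class TestBattery:
    def test_declining_richness_gets_negative_sign_and_is_deterministic(self):
        data, _ = poisson_world(seed=17, n=500, beta1=-0.5, group_sd=0.2,
                                slope_sd=0.1, G=8)
        data = data.rename(columns={"zone": "lat_zone"})
        specs = [ModelSpec(response="richness", predictor="elevation",
                           family="poisson", grouping="lat_zone", seed=17,
                           **FAST)]
        table1, fits1 = run_model_battery(data, specs)
        table2, _ = run_model_battery(data, specs)
        assert table1.loc[0, "beta1_sign"] == "negative"
        pd.testing.assert_frame_equal(table1, table2)

    def test_default_battery_structure(self):
        specs = default_battery(metrics=("richness",),
                                climate_responses=("richness",))
        labels = {s.label() for s in specs}
        assert "richness~elevation[poisson|lat_zone]" in labels
        assert "richness~mat[poisson|lat_zone]" in labels
        assert "richness~mat[poisson|elev_zone]" in labels
        assert "elevation~mat[gaussian|lat_zone]" in labels
        # complementary grouping rule
        for s in specs:
            if s.predictor == "elevation" and s.response == "richness":
                assert s.grouping == "lat_zone"
            if s.predictor == "latitude":
                assert s.grouping == "elev_zone"
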