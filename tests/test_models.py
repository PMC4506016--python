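import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import nbinom

from coastsdm.models import (
    ModelSpec,
    SDModel,
    build_design,
    check_overdispersion,
    fit_gam,
    fit_glm,
    natural_spline_basis,
    predict_model,
    spline_knots,
)


def _binom_frame(n=2000, beta=(0.3, -0.8, 0.5), seed=0):
    rng = np.random.default_rng(seed)
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    eta = beta[0] + beta[1] * x1 + beta[2] * x2
    y = (rng.uniform(size=n) < expit(eta)).astype(float)
    return pd.DataFrame({"x1": x1, "x2": x2, "presence": y})


def _negbin_frame(n=2000, beta=(-0.5, 0.6), theta=1.0, seed=0):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    effort = rng.gamma(2.0, 3.0, size=n) + 0.5
    mu = effort * np.exp(beta[0] + beta[1] * x1)
    y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
    return pd.DataFrame({"x1": x1, "effort_km": effort, "n_sightings": y})


class TestGLM:
    def test_intercept_only_binomial_is_logit_prevalence(self):
        df = _binom_frame(500)
        m = fit_glm(ModelSpec("presence", "binomial"), df)
        prev = df["presence"].mean()
        assert m.params["intercept"] == pytest.approx(np.log(prev / (1 - prev)),
                                                      abs=1e-6)

    def test_binomial_parameter_recovery_within_3se(self):
        df = _binom_frame(2000)
        m = fit_glm(ModelSpec("presence", "binomial", ("x1", "x2")), df)
        truth = {"intercept": 0.3, "x1": -0.8, "x2": 0.5}
        for name, b in truth.items():
            assert abs(m.params[name] - b) < 3 * m._bse[name]

    def test_negbin_parameter_recovery_and_theta(self):
        df = _negbin_frame(4000, theta=1.0, seed=1)
        m = fit_glm(ModelSpec("n_sightings", "negbin", ("x1",)), df)
        assert abs(m.params["intercept"] + 0.5) < 3 * m._bse["intercept"]
        assert abs(m.params["x1"] - 0.6) < 3 * m._bse["x1"]
        assert 0.6 < m.theta < 1.6

    def test_aic_matches_independent_likelihood_evaluation(self):
        # binomial: recompute the Bernoulli log-likelihood by hand
        df = _binom_frame(300, seed=2)
        m = fit_glm(ModelSpec("presence", "binomial", ("x1",)), df)
        eta = m.params["intercept"] + m.params["x1"] * df["x1"]
        p = expit(eta)
        ll = np.sum(df["presence"] * np.log(p) + (1 - df["presence"]) * np.log(1 - p))
        assert m.aic == pytest.approx(-2 * ll + 2 * 2, abs=1e-6)

    def test_negbin_aic_counts_theta_as_parameter(self):
        # recompute the NB2 log-likelihood with scipy at the fitted theta
        df = _negbin_frame(500, seed=3)
        m = fit_glm(ModelSpec("n_sightings", "negbin", ("x1",)), df)
        eta = (m.params["intercept"] + m.params["x1"] * df["x1"]
               + np.log(df["effort_km"]))
        mu = np.exp(eta)
        th = m.theta
        ll = nbinom.logpmf(df["n_sightings"], th, th / (th + mu)).sum()
        k = 2 + 1  # two coefficients plus theta
        assert m.aic == pytest.approx(-2 * ll + 2 * k, abs=1e-3)

    def test_null_model_explained_deviance_is_zero(self):
        df = _binom_frame(200, seed=4)
        m = fit_glm(ModelSpec("presence", "binomial"), df)
        assert m.explained_deviance == pytest.approx(0.0, abs=1e-9)

    def test_nested_model_never_increases_deviance(self):
        df = _binom_frame(300, seed=5)
        m1 = fit_glm(ModelSpec("presence", "binomial", ("x1",)), df)
        m2 = fit_glm(ModelSpec("presence", "binomial", ("x1", "x2")), df)
        assert m2.deviance <= m1.deviance + 1e-8

    def test_offset_rescaling_shifts_only_the_intercept(self):
        df = _negbin_frame(1500, seed=6)
        m1 = fit_glm(ModelSpec("n_sightings", "negbin", ("x1",)), df)
        df2 = df.assign(effort_km=df["effort_km"] * 3.0)
        m2 = fit_glm(ModelSpec("n_sightings", "negbin", ("x1",)), df2)
        assert m2.params["intercept"] == pytest.approx(
            m1.params["intercept"] - np.log(3.0), abs=5e-3)
        assert m2.params["x1"] == pytest.approx(m1.params["x1"], abs=5e-3)

    def test_separated_data_flagged_not_raised(self):
        df = pd.DataFrame({
            "x1": np.r_[np.zeros(20), np.ones(20)],
            "presence": np.r_[np.zeros(20), np.ones(20)],
        })
        m = fit_glm(ModelSpec("presence", "binomial", ("x1",)), df)
        assert not m.converged


class TestGAM:
    def test_spline_design_has_at_most_3_columns_per_term(self):
        df = _binom_frame(100, seed=7)
        spec = ModelSpec("presence", "binomial", ("x1", "x2"), form="gam")
        X, names, _ = build_design(df, spec)
        for var in ("x1", "x2"):
            assert sum(n.startswith(f"s({var})") for n in names) <= 3

    def test_linear_truth_matches_glm_predictions(self):
        df = _binom_frame(5000, seed=8)
        glm = fit_glm(ModelSpec("presence", "binomial", ("x1", "x2")), df)
        gam = fit_gam(ModelSpec("presence", "binomial", ("x1", "x2"),
                                form="gam"), df)
        sweep = pd.DataFrame({
            "x1": np.linspace(-1.5, 1.5, 60), "x2": np.zeros(60),
        })
        p_glm = predict_model(glm, sweep)
        p_gam = predict_model(gam, sweep)
        assert np.max(np.abs(p_glm - p_gam)) < 0.05

    def test_quadratic_truth_favours_the_smooth(self):
        rng = np.random.default_rng(9)
        n = 1500
        x = rng.normal(size=n)
        eta = 0.5 - 1.2 * x ** 2
        y = (rng.uniform(size=n) < expit(eta)).astype(float)
        df = pd.DataFrame({"x1": x, "presence": y})
        glm = fit_glm(ModelSpec("presence", "binomial", ("x1",)), df)
        gam = fit_gam(ModelSpec("presence", "binomial", ("x1",), form="gam"), df)
        assert gam.explained_deviance > glm.explained_deviance

    def test_prediction_reuses_training_knots(self):
        df = _binom_frame(500, seed=10)
        gam = fit_gam(ModelSpec("presence", "binomial", ("x1",), form="gam"), df)
        assert set(gam.knots) == {"x1"}
        new = pd.DataFrame({"x1": [0.0]})
        p = predict_model(gam, new)
        assert 0.0 < p[0] < 1.0

    def test_basis_is_linear_beyond_boundary_knots(self):
        knots = np.array([-1.0, 0.0, 1.0, 2.0])
        far = np.array([5.0, 6.0])
        B = natural_spline_basis(far, knots)
        slope = B[1] - B[0]
        B2 = natural_spline_basis(far + 1.0, knots)
        np.testing.assert_allclose(B2[1] - B2[0], slope, atol=1e-9)


class TestPredict:
    def test_zero_linear_predictor_gives_half(self):
        df = pd.DataFrame({"presence": [0.0, 1.0, 0.0, 1.0]})
        m = fit_glm(ModelSpec("presence", "binomial"), df)
        assert predict_model(m, df)[0] == pytest.approx(0.5)

    def test_count_prediction_scales_with_reference_effort(self):
        df = _negbin_frame(800, seed=11)
        m = fit_glm(ModelSpec("n_sightings", "negbin", ("x1",)), df)
        p1 = predict_model(m, df, reference_effort=1.0)
        p2 = predict_model(m, df, reference_effort=2.0)
        np.testing.assert_allclose(p2, 2.0 * p1)

    def test_dot_product_oracle(self):
        df = _binom_frame(400, seed=12)
        m = fit_glm(ModelSpec("presence", "binomial", ("x1", "x2")), df)
        row = df.iloc[:5]
        eta = (m.params["intercept"] + m.params["x1"] * row["x1"]
               + m.params["x2"] * row["x2"])
        np.testing.assert_allclose(predict_model(m, row), expit(eta), atol=1e-12)

    def test_missing_predictor_named_in_error(self):
        df = _binom_frame(100, seed=13)
        m = fit_glm(ModelSpec("presence", "binomial", ("x1",)), df)
        with pytest.raises(KeyError, match="x1"):
            predict_model(m, df.drop(columns=["x1"]))


class TestOverdispersion:
    def test_poisson_counts_near_one(self):
        rng = np.random.default_rng(14)
        n = 5000
        effort = rng.gamma(2.0, 3.0, size=n) + 0.5
        y = rng.poisson(effort * 0.4)
        df = pd.DataFrame({"n_sightings": y, "effort_km": effort})
        assert check_overdispersion(df, "n_sightings") == pytest.approx(1.0, abs=0.15)

    def test_negbin_counts_flagged(self):
        df = _negbin_frame(5000, theta=0.5, seed=15)
        assert check_overdispersion(df, "n_sightings") > 1.5

    def test_all_zero_degenerate(self):
        df = pd.DataFrame({"n_sightings": np.zeros(50),
                           "effort_km": np.ones(50)})
        assert check_overdispersion(df, "n_sightings") == 0.0


def test_estimator_api_round_trip():
    df = _binom_frame(300, seed=16)
    est = SDModel(response="presence", family="binomial",
                  predictors=("x1", "x2"))
    cloned_params = est.get_params()
    est.fit(df)
    assert est.aic_ == est.model_.aic
    assert SDModel(**cloned_params).get_params() == cloned_params
    p = est.predict(df)
    assert ((p >= 0) & (p <= 1)).all()
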