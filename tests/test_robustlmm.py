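import numpy as np
import pandas as pd
import pytest

from conftest import simulate_lmm_response
from epilag.robustlmm import (ModelSpec, RlrtDesign, exact_rlrt, fit_gaussian,
                              fit_robust_matrices, huber_efficiency,
                              huber_k_for_efficiency, huber_psi,
                              huber_psi_prime, rlrt_null_distribution,
                              rlrt_statistic)


@pytest.fixture(scope="module")
def small_design():
    rng = np.random.default_rng(21)
    n = 400
    X = pd.DataFrame({
        "(Intercept)": np.ones(n),
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
    })
    codes = {"g1": rng.integers(0, 8, n), "g2": rng.integers(0, 5, n)}
    return X, codes


class TestHuber:
    def test_psi_smooth_matches_identity_in_core(self):
        r = np.array([-1.0, 0.0, 0.5, 1.0])
        assert np.allclose(huber_psi(r, 1.345), r)  # |r| <= k - delta

    def test_psi_saturates_at_k(self):
        assert huber_psi(10.0, 1.345) == pytest.approx(1.345)
        assert huber_psi(-10.0, 1.345) == pytest.approx(-1.345)

    def test_psi_is_c1_across_the_blend(self):
        k = 1.345
        xs = np.linspace(k * 0.85, k * 1.15, 400)
        d = huber_psi_prime(xs, k)
        # derivative continuous: no jumps bigger than grid resolution allows
        assert np.max(np.abs(np.diff(d))) < 0.05
        assert d.min() >= -1e-12 and d.max() <= 1.0 + 1e-12

    def test_infinite_k_is_least_squares(self):
        r = np.linspace(-5, 5, 11)
        assert np.allclose(huber_psi(r, np.inf), r)
        assert huber_efficiency(np.inf) == 1.0

    def test_printed_tuning_constant(self):
        assert huber_efficiency(1.345) == pytest.approx(0.95, abs=1e-3)
        assert huber_k_for_efficiency(0.95) == pytest.approx(1.345, abs=5e-4)

    def test_efficiency_monotone_in_k(self):
        ks = [0.5, 1.0, 1.345, 1.69, 3.0]
        effs = [huber_efficiency(k) for k in ks]
        assert np.all(np.diff(effs) > 0)


class TestFitLmm:
    def test_zero_variance_truth_collapses_to_ols(self, small_design):
        """Under a zero random-effect truth the variance components shrink to
        ~0; whenever the REML estimate lands on the zero boundary the fixed
        effects coincide with ordinary least squares."""
        X, codes = small_design
        boundary_checked = 0
        for seed in range(8):
            y = simulate_lmm_response(X, codes, [1.0, 0.5, -0.3],
                                      {"g1": 0.0, "g2": 0.0}, 1.0, seed=seed)
            fit = fit_gaussian(y, X, codes, "REML")
            assert all(t < 0.06 for t in fit.tau2.values())
            if all(t < 1e-8 for t in fit.tau2.values()):
                ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
                assert np.allclose(fit.beta.to_numpy(), ols, atol=1e-6)
                boundary_checked += 1
        assert boundary_checked >= 1

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(22)
        n = 2000
        X = pd.DataFrame({"(Intercept)": np.ones(n), "x1": rng.normal(size=n),
                          "x2": rng.normal(size=n)})
        codes = {"g1": rng.integers(0, 20, n)}
        truth = np.array([0.7, -0.4, 0.9])
        y = simulate_lmm_response(X, codes, truth, {"g1": 0.5}, 1.0, seed=2)
        fit = fit_gaussian(y, X, codes, "REML")
        se = np.sqrt(np.diag(fit.cov_beta))
        assert np.all(np.abs(fit.beta.to_numpy() - truth) < 3 * se)
        assert 0.15 < fit.tau2["g1"] < 1.5
        assert 0.8 < fit.sigma2 < 1.25

    def test_reml_equals_ml_on_balanced_orthogonal_design(self):
        # balanced groups, intercept-only fixed part: both estimators give ybar
        n, q = 240, 6
        codes = {"g": np.repeat(np.arange(q), n // q)}
        X = pd.DataFrame({"(Intercept)": np.ones(n)})
        y = simulate_lmm_response(X, codes, [2.0], {"g": 0.8}, 1.0, seed=3)
        f_reml = fit_gaussian(y, X, codes, "REML")
        f_ml = fit_gaussian(y, X, codes, "ML")
        assert f_reml.beta.iloc[0] == pytest.approx(f_ml.beta.iloc[0], abs=1e-8)

    def test_matches_statsmodels_mixedlm(self, small_design):
        import statsmodels.api as sm
        X, codes = small_design
        y = simulate_lmm_response(X, codes, [1.0, 0.5, -0.3],
                                  {"g1": 0.5, "g2": 0.2}, 1.0, seed=4)
        fit = fit_gaussian(y, X, codes, "REML")
        df = pd.DataFrame({"y": y, "x1": X["x1"], "x2": X["x2"],
                           "g1": codes["g1"], "g2": codes["g2"], "one": 1})
        sm_fit = sm.MixedLM.from_formula(
            "y ~ x1 + x2", groups="one",
            vc_formula={"g1": "0 + C(g1)", "g2": "0 + C(g2)"}, data=df,
        ).fit(reml=True)
        assert np.allclose(fit.beta.to_numpy(), sm_fit.fe_params.to_numpy(), atol=1e-5)
        assert fit.sigma2 == pytest.approx(sm_fit.scale, rel=1e-4)
        assert fit.tau2["g1"] == pytest.approx(sm_fit.vcomp[0], rel=1e-3, abs=1e-4)

    def test_rank_deficiency_names_aliased_columns(self, small_design):
        X, codes = small_design
        X = X.copy()
        X["dup"] = X["x1"] * 2.0
        with pytest.raises(ValueError, match="dup|x1"):
            fit_gaussian(np.zeros(len(X)), X, codes)


class TestFitRobust:
    def test_infinite_k_equals_reml(self, small_design):
        X, codes = small_design
        y = simulate_lmm_response(X, codes, [1.0, 0.5, -0.3],
                                  {"g1": 0.5, "g2": 0.2}, 1.0, seed=5)
        reml = fit_gaussian(y, X, codes, "REML")
        rob = fit_robust_matrices(y, X, codes, np.inf, np.inf)
        assert np.allclose(rob.beta.to_numpy(), reml.beta.to_numpy(), atol=1e-6)
        for g in codes:
            assert rob.tau2[g] == pytest.approx(reml.tau2[g], abs=1e-6)
        assert np.all(rob.obs_weights == 1.0)

    def test_clean_data_robust_close_to_reml(self, small_design):
        X, codes = small_design
        y = simulate_lmm_response(X, codes, [1.0, 0.5, -0.3],
                                  {"g1": 0.5, "g2": 0.2}, 1.0, seed=6)
        reml = fit_gaussian(y, X, codes, "REML")
        rob = fit_robust_matrices(y, X, codes, 1.345, 1.345)
        se = np.sqrt(np.diag(reml.cov_beta))
        assert np.all(np.abs(rob.beta.to_numpy() - reml.beta.to_numpy()) < se)

    def test_weights_in_unit_interval(self, small_design):
        X, codes = small_design
        y = simulate_lmm_response(X, codes, [1.0, 0.5, -0.3],
                                  {"g1": 0.5, "g2": 0.2}, 1.0, seed=7)
        rob = fit_robust_matrices(y, X, codes, 1.345, 1.345)
        assert np.all(rob.obs_weights > 0) and np.all(rob.obs_weights <= 1)
        for v in rob.group_weights.values():
            assert np.all(v > 0) and np.all(v <= 1)

    def test_max_weight_monotone_as_k_decreases(self, small_design):
        X, codes = small_design
        rng = np.random.default_rng(8)
        y = simulate_lmm_response(X, codes, [1.0, 0.5, -0.3],
                                  {"g1": 0.5, "g2": 0.2}, 1.0, seed=8)
        y[rng.choice(len(y), 10, replace=False)] += 8.0
        prev = None
        for k in [np.inf, 5.0, 2.0, 1.345, 1.0]:
            rob = fit_robust_matrices(y, X, codes, k, k)
            mean_w = rob.obs_weights.mean()
            if prev is not None:
                assert mean_w <= prev + 1e-8
            prev = mean_w


class TestExactRlrt:
    def test_spectral_statistic_matches_generic_fitter(self, small_design):
        X, codes = small_design
        one = {"g1": codes["g1"]}
        for seed in range(3):
            y = simulate_lmm_response(X, one, [1.0, 0.5, -0.3],
                                      {"g1": 0.3}, 1.0, seed=seed)
            fast = rlrt_statistic(y, X, one)
            alt = fit_gaussian(y, X, one, "REML").loglik
            null = fit_gaussian(y, X, None, "REML").loglik
            assert fast == pytest.approx(max(0.0, 2 * (alt - null)), abs=1e-4)

    def test_seeded_determinism(self, small_design):
        X, codes = small_design
        spec = ModelSpec(response="y", crossbasis=["x1"], covariates=["x2"],
                         groups=["g1"])
        data = pd.DataFrame({"y": simulate_lmm_response(
            X, {"g1": codes["g1"]}, [1.0, 0.5, -0.3], {"g1": 0.3}, 1.0, seed=9),
            "x1": X["x1"], "x2": X["x2"], "g1": codes["g1"]})
        r1 = exact_rlrt(spec, data, "g1", n_sim=200, seed=5)
        r2 = exact_rlrt(spec, data, "g1", n_sim=200, seed=5)
        assert r1 == r2

    def test_power_at_large_icc(self):
        rng = np.random.default_rng(30)
        n, q = 500, 10
        X = pd.DataFrame({"(Intercept)": np.ones(n), "x": rng.normal(size=n)})
        codes = {"g": rng.integers(0, q, n)}
        null = rlrt_null_distribution(X, codes, 500, seed=31)
        crit = np.quantile(null, 0.95)
        rejections = 0
        reps = 60
        for s in range(reps):
            y = simulate_lmm_response(X, codes, [0.0, 0.0], {"g": 1.0}, 1.0,
                                      seed=100 + s)
            rejections += rlrt_statistic(y, X, codes) > crit
        assert rejections / reps > 0.95

    def test_small_nsim_warns(self, small_design):
        X, codes = small_design
        spec = ModelSpec(response="y", crossbasis=["x1"], covariates=["x2"],
                         groups=["g1"])
        data = pd.DataFrame({"y": np.zeros(len(X)) + np.random.default_rng(0).normal(size=len(X)),
                             "x1": X["x1"], "x2": X["x2"], "g1": codes["g1"]})
        with pytest.warns(UserWarning, match="n_sim"):
            exact_rlrt(spec, data, "g1", n_sim=150, seed=1)
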