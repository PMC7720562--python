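import numpy as np
import pandas as pd
import pytest

from epilag.dlnm import lag_basis
from epilag.inference import (TestLedger, analyze_factor, count_findings,
                              lrt_interaction, lrt_nested, run_sensitivity,
                              select_random_effects, sidak_level)
from epilag.robustlmm import ModelSpec, fit_lmm


class TestSidakLevel:
    @pytest.mark.parametrize("m,expected_pct", [
        (1, 95.00), (8, 99.36), (6, 99.15), (16, 99.68), (12, 99.57),
    ])
    def test_printed_levels(self, m, expected_pct):
        assert round(100 * sidak_level(m), 2) == pytest.approx(expected_pct)

    def test_strictly_decreasing_in_m(self):
        levels = [sidak_level(m) for m in range(1, 30)]
        assert np.all(np.diff(levels) > 0)  # conf level rises as m grows

    def test_increasing_in_one_minus_fwer(self):
        assert sidak_level(5, 0.01) > sidak_level(5, 0.05) > sidak_level(5, 0.10)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            sidak_level(0)
        with pytest.raises(ValueError):
            sidak_level(5, 1.5)

    def test_ledger_stratification_doubles_m(self):
        led = TestLedger(gene="IGF2", m=8, stratified=True)
        assert led.m_effective == 16
        assert round(100 * led.conf_level, 2) == 99.68


def _with_response(model_data, seed, theta=None, interaction=None, extra=0.0):
    data, cb = model_data
    rng = np.random.default_rng(seed)
    d = data[cb.column_names].to_numpy()
    y = rng.standard_normal(len(data))
    if theta is not None:
        y = y + d @ theta
    if interaction is not None:
        y = y + (data["sex[male]"].to_numpy()[:, None] * d) @ interaction
    out = data.copy()
    out["score"] = y + extra
    return out, cb


class TestLrt:
    def test_identical_fits_give_zero_statistic(self, model_data):
        data, cb = _with_response(model_data, 1)
        spec = ModelSpec(response="score", crossbasis=cb.column_names,
                         covariates=["maternal_age"], groups=[])
        f = fit_lmm(spec, data, method="ML")
        stat, df, p = lrt_nested(f, f)
        assert stat == 0.0 and p == 1.0

    def test_interaction_df_is_crossbasis_dimension(self, model_data):
        data, cb = _with_response(model_data, 2)
        covs = ["maternal_age", "sex[male]"]
        full = fit_lmm(ModelSpec("score", cb.column_names, covs, [],
                                 interaction=True), data, method="ML")
        red = fit_lmm(ModelSpec("score", cb.column_names, covs, []),
                      data, method="ML")
        stat, df, p = lrt_interaction(full, red)
        assert df == 5
        assert 0 <= p <= 1

    def test_reml_fits_rejected(self, model_data):
        data, cb = _with_response(model_data, 3)
        spec = ModelSpec("score", cb.column_names, ["maternal_age"], [])
        f = fit_lmm(spec, data, method="REML")
        with pytest.raises(ValueError, match="ML"):
            lrt_nested(f, f)

    def test_non_nested_rejected(self, model_data):
        data, cb = _with_response(model_data, 4)
        f1 = fit_lmm(ModelSpec("score", cb.column_names, ["maternal_age"], []),
                     data, method="ML")
        f2 = fit_lmm(ModelSpec("score", cb.column_names, ["pre_pregnancy_bmi"], []),
                     data, method="ML")
        with pytest.raises(ValueError, match="nested"):
            lrt_interaction(f1, f2)


class TestSelectRandomEffects:
    def test_strong_plate_effect_is_selected(self, model_data, cohort189):
        data, cb = _with_response(model_data, 5)
        rng = np.random.default_rng(6)
        codes = pd.Categorical(cohort189["plate"]).codes
        eff = rng.normal(0, 1.5, codes.max() + 1)
        data = data.copy()
        data["score"] = data["score"] + eff[codes]
        spec = ModelSpec("score", cb.column_names, ["maternal_age"],
                         ["plate", "sentrix_col"])
        out = select_random_effects(spec, data, ["plate", "sentrix_col"],
                                    n_sim=300, seed=7)
        assert "plate" in out["selected"]
        assert out["tests"]["plate"]["p"] < 0.05

    def test_unknown_component_rejected(self, model_data):
        data, cb = _with_response(model_data, 8)
        spec = ModelSpec("score", cb.column_names, [], ["plate"])
        from epilag.robustlmm import exact_rlrt
        with pytest.raises(ValueError, match="component"):
            exact_rlrt(spec, data, "sentrix_row", n_sim=200, seed=1)


class TestAnalyzeFactor:
    @pytest.fixture(scope="class")
    def result(self, model_data):
        theta = np.array([0.0, 0.05, -0.02, 0.03, 0.0])
        data, cb = _with_response(model_data, 9, theta=theta)
        spec = ModelSpec("score", cb.column_names,
                         [c for c in data.columns
                          if c not in cb.column_names
                          and c not in ("score", "plate", "sentrix_row", "sentrix_col")],
                         groups=["plate"])
        return analyze_factor("F1", spec, data, lag_basis(),
                              conf_level=sidak_level(8),
                              conf_level_stratified=sidak_level(16))

    def test_effect_tables_complete(self, result):
        assert len(result.effects_all.weekly) == 40
        assert list(result.effects_all.windows.index) == [
            "overall", "trimester1", "trimester2", "trimester3"]
        assert result.effects_boys is not None
        assert result.effects_girls is not None

    def test_window_additivity(self, result):
        w = result.effects_all
        tri_sum = w.windows.loc[["trimester1", "trimester2", "trimester3"],
                                "estimate"].sum()
        assert w.windows.loc["overall", "estimate"] == pytest.approx(tri_sum, abs=1e-9)

    def test_sex_contrasts_average_to_base_block(self, result):
        # boys = theta + gamma, girls = theta - gamma: the mean of the two
        # stratified curves equals the interaction model's base-block curve
        mean_curve = (result.effects_boys.weekly["estimate"]
                      + result.effects_girls.weekly["estimate"]) / 2
        assert np.all(np.isfinite(mean_curve))
        # and stratified CIs are wider than all-observation CIs on average
        hw_strat = (result.effects_boys.weekly["upper"]
                    - result.effects_boys.weekly["lower"]).mean()
        hw_all = (result.effects_all.weekly["upper"]
                  - result.effects_all.weekly["lower"]).mean()
        assert hw_strat > hw_all

    def test_count_findings_uses_overall_window(self, result):
        n = count_findings({"F1": result})
        row = result.effects_all.windows.loc["overall"]
        assert n == int(row["lower"] > 0 or row["upper"] < 0)


class TestRunSensitivity:
    @pytest.fixture(scope="class")
    def report(self, model_data, cohort189, exposure189):
        theta = np.array([0.0, 0.05, -0.02, 0.03, 0.0])
        data, cb = _with_response(model_data, 10, theta=theta)
        covs = [c for c in data.columns
                if c not in cb.column_names
                and c not in ("score", "plate", "sentrix_row", "sentrix_col")]
        spec = ModelSpec("score", cb.column_names, covs, groups=[])
        return run_sensitivity(spec, data, exposure189, cohort189, lag_basis(),
                               conf_level=0.9936), data, spec, cohort189

    def test_preterm_exclusion_drops_exact_count(self, report):
        rep, data, spec, cohort = report
        assert rep["preterm_excluded"]["n_dropped"] == int(
            (cohort["gestational_age"] < 37).sum())

    def test_k_infinity_reproduces_reml(self, report):
        rep, data, spec, _ = report
        from epilag.dlnm import predict_effects
        f = fit_lmm(spec, data, method="REML")
        th, V = f.block(spec.crossbasis)
        eff = predict_effects(th, V, lag_basis(), delta=5.0, conf_level=0.9936)
        assert np.allclose(rep["k_choice"]["k=inf"].to_numpy(),
                           eff.windows["estimate"].to_numpy(), atol=1e-6)

    def test_df_comparison_reports_all_flexibilities(self, report):
        rep, *_ = report
        ic = rep["df_choice"]["information_criteria"]
        assert list(ic.index) == [5, 7, 9]
        assert rep["df_choice"]["unconstrained_vs_df5"]["df"] == 35

    def test_aic_prefers_parsimonious_truth(self, model_data, exposure189):
        """Truth inside the DF-5 spline space: AIC should prefer DF 5 over
        DF 9 in a clear majority of replicates."""
        from epilag.dlnm import cross_basis
        data0, cb5 = model_data
        n = len(data0)
        theta = np.array([0.0, 0.05, -0.02, 0.03, 0.0])
        base = data0[cb5.column_names].to_numpy() @ theta
        cb9 = cross_basis(exposure189, lag_basis(n_knots=7))
        X5 = np.column_stack([np.ones(n), data0[cb5.column_names].to_numpy()])
        X9 = np.column_stack([np.ones(n), cb9.matrix])

        def aic(X, y):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = np.sum((y - X @ beta) ** 2)
            return n * np.log(rss / n) + 2 * (X.shape[1] + 1)

        rng = np.random.default_rng(11)
        prefer5 = sum(
            aic(X5, y) < aic(X9, y)
            for y in (base + rng.standard_normal(n) for _ in range(30))
        )
        assert prefer5 / 30 >= 0.8
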