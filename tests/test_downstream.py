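import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epilag import synthdata as sd
from epilag.downstream import (correlate_transcripts, growth_regression,
                               last3_mean_exposure, mediate, ora, read_gmt,
                               write_gmt)


@pytest.fixture(scope="module")
def covs():
    rng = np.random.default_rng(60)
    n = 189
    return pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"),
                        index=[f"S{i:04d}" for i in range(n)])


class TestGrowthRegression:
    def test_type_one_error_calibrated(self, covs):
        rng = np.random.default_rng(61)
        n = len(covs)
        hits = 0
        reps = 400
        for _ in range(reps):
            score = pd.Series(rng.standard_normal(n), index=covs.index)
            outcome = pd.Series(2.69 + 0.2 * rng.standard_normal(n), index=covs.index)
            *_, p = growth_regression(outcome, score, covs)
            hits += p < 0.05
        assert 0.03 < hits / reps < 0.07

    def test_small_negative_effect_sign_recovered_in_majority(self, covs):
        rng = np.random.default_rng(62)
        n = len(covs)
        neg = 0
        reps = 60
        for _ in range(reps):
            score = pd.Series(rng.standard_normal(n), index=covs.index)
            outcome = pd.Series(2.69 - 0.05 * score + 0.2 * rng.standard_normal(n),
                                index=covs.index)
            coef, *_ = growth_regression(outcome, score, covs)
            neg += coef < 0
        assert neg / reps > 0.5

    def test_outcome_shift_leaves_slope_unchanged(self, covs):
        rng = np.random.default_rng(63)
        n = len(covs)
        score = pd.Series(rng.standard_normal(n), index=covs.index)
        outcome = pd.Series(rng.standard_normal(n), index=covs.index)
        c1, s1, p1 = growth_regression(outcome, score, covs)
        c2, s2, p2 = growth_regression(outcome + 100.0, score, covs)
        assert c1 == pytest.approx(c2) and p1 == pytest.approx(p2)


class TestMediate:
    def test_noise_free_closed_form(self, covs):
        # mediator noise built exactly orthogonal to [1, exposure, covariate]
        # so a-hat = 0.5 exactly; outcome exactly 0.5 * mediator so b-hat = 0.5
        rng = np.random.default_rng(64)
        n = len(covs)
        e = pd.Series(rng.standard_normal(n), index=covs.index)
        C1 = covs.iloc[:, :1]
        Xm = np.column_stack([np.ones(n), e.to_numpy(), C1.to_numpy()])
        w = rng.standard_normal(n)
        w -= Xm @ np.linalg.lstsq(Xm, w, rcond=None)[0]
        m = pd.Series(0.5 * e.to_numpy() + w, index=covs.index)
        y = pd.Series(0.5 * m, index=covs.index)
        res = mediate(e, m, y, C1, n_boot=500, seed=1)
        assert res.a == pytest.approx(0.5, abs=1e-10)
        assert res.b == pytest.approx(0.5, abs=1e-10)
        assert res.indirect == pytest.approx(0.25, abs=1e-10)

    def test_total_effect_decomposition_identity(self, covs):
        rng = np.random.default_rng(65)
        n = len(covs)
        e = pd.Series(rng.standard_normal(n), index=covs.index)
        m = pd.Series(0.4 * e + rng.standard_normal(n), index=covs.index)
        y = pd.Series(0.3 * m + 0.2 * e + rng.standard_normal(n), index=covs.index)
        res = mediate(e, m, y, covs, n_boot=500, seed=2)
        assert res.total == pytest.approx(res.c_prime + res.indirect, abs=1e-10)

    def test_contrast_scheme_invariance(self, covs):
        # replacing covariates by an invertible affine transform leaves paths alone
        rng = np.random.default_rng(66)
        n = len(covs)
        e = pd.Series(rng.standard_normal(n), index=covs.index)
        m = pd.Series(0.4 * e + rng.standard_normal(n), index=covs.index)
        y = pd.Series(0.3 * m + rng.standard_normal(n), index=covs.index)
        A = np.array([[1.0, 2.0, 0.0], [0.0, 1.0, 0.0], [1.0, 0.0, 3.0]])
        covs2 = pd.DataFrame(covs.to_numpy() @ A + 5.0, index=covs.index)
        r1 = mediate(e, m, y, covs, n_boot=500, seed=3)
        r2 = mediate(e, m, y, covs2, n_boot=500, seed=3)
        assert r1.indirect == pytest.approx(r2.indirect, abs=1e-10)

    def test_rejects_small_bootstrap(self, covs):
        e = pd.Series(np.zeros(len(covs)), index=covs.index)
        with pytest.raises(ValueError):
            mediate(e, e, e, covs, n_boot=100)

    def test_last3_window_respects_gestational_age(self):
        cohort = sd.generate_cohort(100, seed=67)
        expo = sd.generate_exposure(cohort, seed=68)
        out = last3_mean_exposure(expo, cohort)
        sid = cohort.index[0]
        g = cohort.loc[sid, "gestational_age"]
        manual = expo.loc[sid].to_numpy()[g - 3:g].mean()
        assert out.loc[sid] == pytest.approx(manual)


class TestCorrelateTranscripts:
    def test_perfect_transcript_ranks_first(self):
        rng = np.random.default_rng(70)
        n = 100
        score = pd.Series(rng.standard_normal(n),
                          index=[f"S{i}" for i in range(n)])
        E = rng.standard_normal((20, n))
        E[7] = score.to_numpy()
        expr = pd.DataFrame(E, index=[f"T{i}" for i in range(20)],
                            columns=score.index)
        table, selected = correlate_transcripts(score, expr)
        assert table.index[0] == "T7"
        assert table.iloc[0]["p"] < 1e-50

    def test_noise_selection_rate_and_truncation(self):
        rng = np.random.default_rng(71)
        n = 189
        score = pd.Series(rng.standard_normal(n),
                          index=[f"S{i}" for i in range(n)])
        expr = pd.DataFrame(rng.standard_normal((5000, n)),
                            index=[f"T{i}" for i in range(5000)],
                            columns=score.index)
        table, selected = correlate_transcripts(score, expr)
        n_pass = (table["p"] < 0.05).sum()
        assert 190 < n_pass < 310  # ~0.05 * 5000 before truncation
        assert len(selected) == 100

    def test_hand_computed_pearson_on_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        # hand oracle: r = cov(x,y)/(sd x sd y), computed independently
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean())**2).sum() * ((y - y.mean())**2).sum()))
        score = pd.Series(x, index=list("abcde"))
        expr = pd.DataFrame([y], index=["T0"], columns=list("abcde"))
        table, _ = correlate_transcripts(score, expr)
        assert table.loc["T0", "r"] == pytest.approx(r_hand, abs=1e-12)

    def test_constant_transcript_warns_with_p_one(self):
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        expr = pd.DataFrame([[5.0, 5.0, 5.0, 5.0]], index=["T0"],
                            columns=list("abcd"))
        with pytest.warns(UserWarning, match="constant"):
            table, selected = correlate_transcripts(score, expr)
        assert table.loc["T0", "p"] == 1.0
        assert selected == []

    def test_misaligned_samples_rejected(self):
        score = pd.Series([1.0, 2.0], index=["a", "b"])
        expr = pd.DataFrame([[1.0, 2.0]], index=["T0"], columns=["a", "c"])
        with pytest.raises(ValueError, match="align"):
            correlate_transcripts(score, expr)


class TestOra:
    def test_matches_exact_tail_enumeration(self):
        from math import comb
        N, K, n, k = 100, 10, 10, 5
        expected = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / comb(N, n)
        universe = [f"G{i}" for i in range(N)]
        selected = universe[:5] + universe[50:55]
        gene_set = {"S": universe[:10]}
        out = ora(selected, gene_set, universe)
        assert out.loc["S", "p"] == pytest.approx(expected, rel=1e-12)

    def test_zero_overlap_not_significant(self):
        universe = [f"G{i}" for i in range(50)]
        out = ora(universe[:5], {"S": universe[40:45]}, universe)
        assert out.loc["S", "p"] == pytest.approx(1.0)
        assert not out.loc["S", "significant"]

    def test_min_overlap_rule_blocks_tiny_sets(self):
        universe = [f"G{i}" for i in range(1000)]
        out = ora(universe[:2], {"S": universe[:2]}, universe)
        assert out.loc["S", "p"] < 0.01
        assert out.loc["S", "overlap"] == 2
        assert not out.loc["S", "significant"]

    def test_p_monotone_in_overlap(self):
        universe = [f"G{i}" for i in range(200)]
        ps = []
        for k in range(1, 6):
            sel = universe[:k] + universe[100:100 + (10 - k)]
            ps.append(ora(sel, {"S": universe[:20]}, universe).loc["S", "p"])
        assert np.all(np.diff(ps) <= 1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora([], {"S": ["G1"]}, [])

    def test_gmt_roundtrip(self, tmp_path):
        sets = {"A": ["G1", "G2"], "B": ["G3"]}
        p = tmp_path / "x.gmt"
        write_gmt(sets, p)
        assert read_gmt(p) == sets
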