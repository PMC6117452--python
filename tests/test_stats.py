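"""Standardized regressions, coefficient tests, correction, BIC comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from metaddm import stats as st


def _planted_table(n=5000, seed=0, b1=0.3, b2=-0.2, noise=1.0):
    rng = np.random.default_rng(seed)
    x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
    y = b1 * x1 + b2 * x2 + noise * rng.standard_normal(n)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2,
                         "age": rng.uniform(18, 70, n),
                         "iq": rng.normal(100, 15, n),
                         "gender": rng.integers(0, 2, n)})


class TestZscore:
    def test_simple_example(self):
        assert np.allclose(st.zscore([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        z = st.zscore(rng.normal(size=100))
        assert np.abs(st.zscore(z) - z).max() < 1e-12

    def test_zero_variance_rejected_with_name(self):
        with pytest.raises(ValueError, match="iq"):
            st.zscore([2, 2, 2], name="iq")

    @given(a=st_h.floats(0.1, 10), b=st_h.floats(-5, 5))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.1, -2.0, 4.5, 0.0])
        assert np.allclose(st.zscore(a * x + b), st.zscore(x), atol=1e-9)


class TestFitOLS:
    def test_exact_fit(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4, 5], "x": [1.0, 2, 3, 4, 5]})
        r = st.fit_ols(df, "y", ["x"])
        assert r.beta("x") == pytest.approx(1.0) and r.r2 == pytest.approx(1.0)

    def test_planted_coefficients_consistent(self):
        df = _planted_table()
        r = st.fit_ols(df, "y", ["x1", "x2"])
        # standardized truth: beta / sd(y)
        sd_y = np.sqrt(0.3 ** 2 + 0.2 ** 2 + 1.0)
        assert r.beta("x1") == pytest.approx(0.3 / sd_y, abs=0.04)
        assert r.beta("x2") == pytest.approx(-0.2 / sd_y, abs=0.04)

    def test_null_predictor_small_beta(self):
        df = _planted_table(b1=0.0, b2=0.0)
        r = st.fit_ols(df, "y", ["x1", "x2"])
        assert abs(r.beta("x1")) < 0.04

    def test_single_predictor_beta_equals_pearson_r(self):
        df = _planted_table(n=400, seed=3)
        r = st.fit_ols(df, "y", ["x1"])
        pearson = np.corrcoef(df["y"], df["x1"])[0, 1]
        assert r.beta("x1") == pytest.approx(pearson, abs=1e-10)

    def test_bic_identity(self):
        df = _planted_table(n=300, seed=4)
        r = st.fit_ols(df, "y", ["x1", "x2", "age"])
        assert r.bic == pytest.approx(-2 * r.loglik + r.k_params * np.log(r.n))

    def test_rank_deficiency_named(self):
        df = _planted_table(n=100, seed=5)
        df["x1_copy"] = df["x1"]
        with pytest.raises(ValueError, match="collinear"):
            st.fit_ols(df, "y", ["x1", "x1_copy"])

    def test_outcome_scale_invariance(self):
        df = _planted_table(n=400, seed=6)
        r1 = st.fit_ols(df, "y", ["x1", "x2"])
        df2 = df.assign(y=df["y"] * 2.0)
        r2 = st.fit_ols(df2, "y", ["x1", "x2"])
        assert np.allclose(r1.betas, r2.betas, atol=1e-12)


class TestSymptomGrid:
    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(7)
        n = 500
        anx = rng.standard_normal(n)
        df = pd.DataFrame({
            "anxiety": anx,
            "conf_level": -0.15 * anx + np.sqrt(1 - 0.15 ** 2) * rng.standard_normal(n),
            "accuracy": rng.standard_normal(n),
            "age": rng.uniform(18, 70, n), "iq": rng.normal(100, 15, n),
            "gender": rng.integers(0, 2, n)})
        grid = st.run_symptom_regressions(df, ["anxiety"],
                                          ["accuracy", "conf_level"])
        r = grid[("conf_level", "anxiety")]
        assert r.beta("anxiety") == pytest.approx(-0.15, abs=0.05)
        assert abs(grid[("accuracy", "anxiety")].beta("anxiety")) < 0.1

    def test_row_shuffle_invariance(self):
        df = _planted_table(n=300, seed=8).rename(columns={"x1": "symptom"})
        g1 = st.run_symptom_regressions(df, ["symptom"], ["y"])
        df2 = df.sample(frac=1.0, random_state=1)
        g2 = st.run_symptom_regressions(df2, ["symptom"], ["y"])
        assert g1[("y", "symptom")].beta("symptom") == pytest.approx(
            g2[("y", "symptom")].beta("symptom"), abs=1e-12)

    def test_missing_covariate_rejected(self):
        df = _planted_table(n=50).drop(columns="iq")
        with pytest.raises(ValueError, match="iq"):
            st.run_symptom_regressions(df, ["x1"], ["y"])


class TestCompareCoefficients:
    def test_identical_effects_large_p(self):
        rng = np.random.default_rng(9)
        n = 400
        x = rng.standard_normal(n)
        df = pd.DataFrame({"y": x + rng.standard_normal(n) * 0.5,
                           "p1": x, "p2": x + 1e-8 * rng.standard_normal(n)})
        # jittered duplicates: identical effects, difference is pure noise
        p = st.compare_coefficients(df, "y", ["p1", "p2"], "p1", "p2",
                                    b=400, seed=0)
        assert p > 0.2

    def test_opposite_effects_separated(self):
        rng = np.random.default_rng(10)
        n = 500
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        df = pd.DataFrame({"y": 0.3 * x1 - 0.3 * x2 + rng.standard_normal(n),
                           "p1": x1, "p2": x2})
        p = st.compare_coefficients(df, "y", ["p1", "p2"], "p1", "p2",
                                    b=1000, seed=1)
        assert p < 0.01
        # but the absolute magnitudes do not differ
        p_abs = st.compare_coefficients(df, "y", ["p1", "p2"], "p1", "p2",
                                        b=1000, seed=2, absolute=True)
        assert p_abs > 0.05

    def test_deterministic_given_seed(self):
        df = _planted_table(n=200, seed=11)
        args = (df, "y", ["x1", "x2"], "x1", "x2")
        assert st.compare_coefficients(*args, b=200, seed=5) == \
            st.compare_coefficients(*args, b=200, seed=5)

    def test_too_few_replicates_rejected(self):
        df = _planted_table(n=100, seed=12)
        with pytest.raises(ValueError):
            st.compare_coefficients(df, "y", ["x1", "x2"], "x1", "x2", b=50)


class TestCorrection:
    @pytest.mark.parametrize("p,m,expected", [
        (0.01, 4, 0.04), (0.4, 5, 1.0), (0.2, 1, 0.2)])
    def test_bonferroni(self, p, m, expected):
        assert st.correct_pvalues([p], m)[0] == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.correct_pvalues([1.2], 3)

    @given(p=st_h.floats(0, 1), m=st_h.integers(1, 50))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_adjusted_in_unit_interval(self, p, m):
        q = st.correct_pvalues([p], m)[0]
        assert 0 <= q <= 1 and q >= p


class TestModelComparison:
    def test_nested_identical_fit_exact_penalty(self):
        # outcome independent of everything: same loglik up to noise; use
        # duplicate-information predictors to force literally identical fit
        rng = np.random.default_rng(13)
        n = 200
        df = pd.DataFrame({"y": rng.standard_normal(n),
                           "age": rng.uniform(18, 70, n),
                           "iq": rng.normal(100, 15, n),
                           "gender": rng.integers(0, 2, n)})
        # factors orthogonal to y by construction: project out
        simple = st.fit_ols(df, "y", ["age", "iq", "gender"])
        for j, f in enumerate(("AD", "CIT", "SW")):
            df[f] = 0.5 * df["age"] + rng.standard_normal(n)
        full = st.fit_ols(df, "y", ["AD", "CIT", "SW", "age", "iq", "gender"])
        # identity check on the formula rather than the fit:
        assert full.bic - simple.bic == pytest.approx(
            -2 * (full.loglik - simple.loglik) + 3 * np.log(n))

    def test_parsimony_favors_simple_under_null(self):
        wins = 0
        for seed in range(25):
            rng = np.random.default_rng(100 + seed)
            n = 500
            age = rng.uniform(18, 70, n)
            df = pd.DataFrame({
                "y": 0.3 * st.zscore(age) + rng.standard_normal(n),
                "age": age, "iq": rng.normal(100, 15, n),
                "gender": rng.integers(0, 2, n),
                "AD": rng.standard_normal(n), "CIT": rng.standard_normal(n),
                "SW": rng.standard_normal(n)})
            if st.compare_models(df, "y").delta_bic > 0:
                wins += 1
        assert wins >= 23  # >= 90% of cohorts

    def test_planted_factor_effects_favor_full(self):
        wins = 0
        for seed in range(25):
            rng = np.random.default_rng(200 + seed)
            n = 500
            ad, cit, sw = rng.standard_normal((3, n))
            df = pd.DataFrame({
                "y": -0.2 * ad + 0.23 * cit + 0.95 * rng.standard_normal(n),
                "age": rng.uniform(18, 70, n), "iq": rng.normal(100, 15, n),
                "gender": rng.integers(0, 2, n),
                "AD": ad, "CIT": cit, "SW": sw})
            if st.compare_models(df, "y").delta_bic < 0:
                wins += 1
        assert wins >= 23

    def test_delta_bic_sign_convention(self):
        df = _planted_table(n=300, seed=14)
        df[["AD", "CIT", "SW"]] = np.random.default_rng(0).standard_normal((300, 3))
        c = st.compare_models(df, "y")
        assert c.delta_bic == pytest.approx(c.bic_full - c.bic_simple)
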