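"""Synthetic cohort generator: genotypes, trials, confidence, staircase, items."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from metaddm import cohort as coh
from metaddm import stats as st
from metaddm.metacog import score_subject


class TestSampleCohort:
    def test_null_effects_constant_bias(self):
        spec = coh.CohortSpec(n_subjects=50, beta_conf=(0, 0, 0),
                              beta_eff=(0, 0, 0), noise_sd=0.0, seed=1)
        cohort = coh.sample_cohort(spec)
        assert np.allclose([g.conf_bias_true for g in cohort], 0.0)
        assert np.allclose([g.m_ratio_true for g in cohort],
                           coh.GenotypeRanges().m_ratio_baseline)

    def test_determinism_same_seed(self):
        spec = coh.CohortSpec(n_subjects=20, seed=7)
        c1 = coh.sample_cohort(spec)
        c2 = coh.sample_cohort(spec)
        for g1, g2 in zip(c1, c2):
            assert g1.__dict__.keys() == g2.__dict__.keys()
            assert np.array_equal(g1.f_scores, g2.f_scores)
            assert (g1.a, g1.t_nd, g1.conf_bias_true) == (g2.a, g2.t_nd, g2.conf_bias_true)

    def test_planted_betas_recovered_by_ols(self):
        spec = coh.CohortSpec(n_subjects=8000, beta_conf=(-0.2, 0.23, 0.0), seed=5)
        cohort = coh.sample_cohort(spec)
        ranges = coh.GenotypeRanges()
        df = pd.DataFrame({
            "bias": [g.conf_bias_true / ranges.bias_scale for g in cohort],
            "AD": [g.f_scores[0] for g in cohort],
            "CIT": [g.f_scores[1] for g in cohort],
            "SW": [g.f_scores[2] for g in cohort]})
        r = st.fit_ols(df, "bias", ["AD", "CIT", "SW"])
        assert np.abs(r.betas - np.array([-0.2, 0.23, 0.0])).max() < 0.03

    def test_invalid_ranges_rejected(self):
        bad = coh.GenotypeRanges(a=(-1.0, 2.0))
        with pytest.raises(ValueError):
            coh.sample_cohort(coh.CohortSpec(n_subjects=5), bad)

    def test_trials_not_divisible_by_blocks_rejected(self):
        with pytest.raises(ValueError):
            coh.CohortSpec(n_subjects=5, n_trials=211, n_blocks=5)


class TestSimulateTrials:
    def test_zero_drift_near_chance(self, base_genotype):
        from dataclasses import replace
        g = replace(base_genotype, v0=0.0, v_delta=0.0)
        t = coh.simulate_trials(g, np.tile([2.0, 8.0, 32.0], 2000), seed=2)
        assert abs(t["accuracy"].mean() - 0.5) < 0.02

    def test_all_rt_exceed_nondecision_time(self, base_genotype):
        t = coh.simulate_trials(base_genotype, np.tile([2.0, 8.0, 32.0], 50), seed=3)
        assert (t["rt"] > base_genotype.t_nd).all()

    def test_determinism(self, base_genotype):
        d = np.tile([2.0, 8.0, 32.0], 20)
        t1 = coh.simulate_trials(base_genotype, d, seed=4)
        t2 = coh.simulate_trials(base_genotype, d, seed=4)
        pd.testing.assert_frame_equal(t1, t2)

    def test_choice_consistent_with_stimulus_and_accuracy(self, base_genotype):
        t = coh.simulate_trials(base_genotype, np.tile([2.0, 8.0, 32.0], 40), seed=5)
        correct = t["choice"] == t["stimulus"]
        assert (correct == (t["accuracy"] == 1)).all()


class TestAssignConfidence:
    def test_rejects_single_level(self, base_genotype, rated_trials):
        with pytest.raises(ValueError):
            coh.assign_confidence(rated_trials, base_genotype, n_levels=1)

    def test_ratings_within_scale(self, rated_trials):
        assert rated_trials["conf_raw"].between(1, 6).all()

    def test_mean_confidence_monotone_in_bias(self, base_genotype):
        from dataclasses import replace
        deltas = np.tile([2.0, 4.0, 8.0, 16.0, 32.0], 400)
        tab = coh.simulate_trials(base_genotype, deltas, seed=6)
        means = []
        for bias in (-0.5, 0.0, 0.5, 1.0):
            g = replace(base_genotype, conf_bias_true=bias)
            means.append(coh.assign_confidence(tab, g, 6, seed=7)["conf_raw"].mean())
        assert (np.diff(means) >= 0).all()

    def test_m_ratio_round_trip(self, base_genotype):
        from dataclasses import replace
        deltas = np.tile([2.0, 4.0, 8.0, 16.0, 32.0], 2000)
        for true_mr, seed in ((0.5, 31), (1.0, 33)):
            g = replace(base_genotype, m_ratio_true=true_mr)
            t = coh.simulate_trials(g, deltas, seed=seed)
            t = coh.assign_confidence(t, g, 6, seed=seed + 1)
            m = score_subject(t, scale=(1, 6))
            assert m.m_ratio == pytest.approx(true_mr, abs=0.1)

    def test_zero_efficiency_uninformative(self, base_genotype):
        from dataclasses import replace
        g = replace(base_genotype, m_ratio_true=0.0)
        t = coh.simulate_trials(g, np.tile([2.0, 4.0, 8.0, 16.0, 32.0], 1200),
                                seed=35)
        t = coh.assign_confidence(t, g, 6, seed=36)
        m = score_subject(t, scale=(1, 6))
        assert abs(m.meta_d) < 0.15


class TestBiasEfficiencyIndependence:
    @pytest.mark.filterwarnings("ignore:constant ratings:UserWarning")
    def test_fitted_measures_decoupled_under_null_effects(self):
        # bias and efficiency are drawn independently; the fitted confidence
        # level and M-ratio must stay decoupled across the cohort
        from metaddm.validation import independence_check
        assert abs(independence_check(seed=0, n_subjects=600)) < 0.1


class TestStaircase:
    def test_accuracy_span_under_fourfold_sensitivity_spread(self):
        from metaddm.validation import staircase_accuracy_span
        span, _ = staircase_accuracy_span(seed=0)
        assert span < 0.06


    def test_two_down_rule_definition(self):
        rule = coh.StaircaseRule()
        s = coh.StaircaseState(log_delta=math.log(8.0), step=rule.initial_step,
                               n_correct_streak=1)
        s2 = coh.staircase_step(s, correct=1, rule=rule)
        assert s2.n_correct_streak == 0
        assert s2.log_delta == pytest.approx(math.log(8.0) - rule.initial_step)
        # a single correct response only increments the streak
        s3 = coh.staircase_step(coh.StaircaseState(math.log(8.0), rule.initial_step),
                                correct=1, rule=rule)
        assert s3.n_correct_streak == 1
        assert s3.log_delta == pytest.approx(math.log(8.0))

    def test_error_at_upper_bound_clamps_and_counts_reversal(self):
        rule = coh.StaircaseRule(bounds=(1.0, 64.0))
        s = coh.StaircaseState(log_delta=math.log(64.0), step=rule.initial_step,
                               last_direction=-1)
        s2 = coh.staircase_step(s, correct=0, rule=rule)
        assert s2.delta == pytest.approx(64.0)
        assert s2.n_reversals == 1

    def test_step_halves_after_first_reversals(self):
        rule = coh.StaircaseRule()
        s = coh.StaircaseState(math.log(8.0), rule.initial_step, last_direction=-1)
        s2 = coh.staircase_step(s, correct=0, rule=rule)
        assert s2.step == pytest.approx(rule.initial_step / 2)

    def test_convergence_near_707(self, base_genotype):
        df = coh.run_staircase_session(base_genotype, 1000, seed=9,
                                       mode="bernoulli")
        assert df["accuracy"].iloc[200:].mean() == pytest.approx(0.707, abs=0.03)

    @given(seq=st_h.lists(st_h.integers(0, 1), min_size=1, max_size=200))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_delta_always_within_bounds(self, seq):
        rule = coh.StaircaseRule(bounds=(1.0, 64.0))
        s = coh.StaircaseState(math.log(8.0), rule.initial_step)
        for corr in seq:
            s = coh.staircase_step(s, corr, rule)
            assert 1.0 - 1e-9 <= s.delta <= 64.0 + 1e-9
            assert s.n_reversals >= 0 and s.n_correct_streak >= 0


class TestQuestionnaires:
    def test_dichotomous_items_binary(self):
        fm = coh.default_factor_model()
        fm2 = coh.FactorModelSpec(fm.loadings, fm.factor_corr, fm.uniquenesses,
                                  np.full(fm.n_items, 2), fm.item_to_questionnaire)
        items = coh.simulate_questionnaires(fm2, np.zeros((20, 3)), seed=1)
        vals = items.drop(columns="subject").to_numpy()
        assert set(np.unique(vals)) <= {0, 1}

    def test_orthogonal_blocks_uncorrelated(self):
        # 3 disjoint blocks of items, identity factor correlation
        lam = np.zeros((30, 3))
        for j in range(3):
            lam[j * 10:(j + 1) * 10, j] = 0.7
        fm = coh.FactorModelSpec(lam, np.eye(3), 1 - (lam ** 2).sum(1),
                                 np.full(30, 4), ["q"] * 30)
        rng = np.random.default_rng(8)
        f = rng.standard_normal((5000, 3))
        items = coh.simulate_questionnaires(fm, f, seed=9)
        r = np.corrcoef(items.drop(columns="subject").to_numpy(float), rowvar=False)
        between = r[:10, 10:20]
        assert np.abs(between).max() < 0.05

    def test_empirical_correlation_converges_to_implied(self, planted_factor_data):
        fm, f, items = planted_factor_data
        emp = np.corrcoef(items.drop(columns="subject").to_numpy(float),
                          rowvar=False)
        imp = fm.implied_correlation()
        off = ~np.eye(fm.n_items, dtype=bool)
        # ordinal cutting attenuates Pearson correlations by a near-uniform
        # factor; compare after rescaling by the median attenuation
        ratio = np.median(emp[off] / np.where(np.abs(imp[off]) < 1e-12, np.nan,
                                              imp[off]))
        dev = np.abs(emp[off] - ratio * imp[off])
        assert np.nanmean(dev) < 0.03
        assert np.nanpercentile(dev, 99.5) < 0.08

    def test_zero_loading_row_warns(self):
        lam = np.zeros((10, 3))
        lam[1:, 0] = 0.6
        with pytest.warns(UserWarning):
            coh.FactorModelSpec(lam, np.eye(3), np.full(10, 0.5),
                                np.full(10, 4), ["q"] * 10)

    def test_determinism(self):
        fm = coh.default_factor_model()
        f = np.zeros((10, 3))
        pd.testing.assert_frame_equal(
            coh.simulate_questionnaires(fm, f, seed=3),
            coh.simulate_questionnaires(fm, f, seed=3))
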