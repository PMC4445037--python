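"""DerSimonian-Laird pooling, heterogeneity statistics, and Begg's test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dosenma.effect_sizes import ContrastEstimate
from dosenma.pairwise import beggs_test, dl_pool


def est(y, v, study="S", scale="smd"):
    return ContrastEstimate(study_id=study, comparison=("C200QD", "PBO"),
                            effect=y, variance=v, scale=scale)


def make_estimates(ys, vs, scale="smd"):
    return [est(y, v, study=f"S{i}", scale=scale)
            for i, (y, v) in enumerate(zip(ys, vs))]


class TestDLPool:
    def test_two_study_worked_example(self):
        # y = {0, 1}, v = {0.1, 0.1}: Q = 5, tau2 = 4/10 = 0.4, pooled = 0.5
        res = dl_pool(make_estimates([0.0, 1.0], [0.1, 0.1]))
        assert res.Q == pytest.approx(5.0, rel=1e-12)
        assert res.tau2 == pytest.approx(0.4, rel=1e-12)
        assert res.pooled_effect == pytest.approx(0.5, rel=1e-12)
        assert res.I2 == pytest.approx(100 * (5 - 1) / 5)

    def test_single_study_contract(self):
        res = dl_pool(make_estimates([0.3], [0.04]))
        assert res.pooled_effect == pytest.approx(0.3)
        assert res.ci95 == pytest.approx((0.3 - 1.96 * 0.2, 0.3 + 1.96 * 0.2))
        assert res.tau2 == 0.0 and res.Q == 0.0 and res.I2 == 0.0

    def test_identical_studies_have_no_dispersion(self):
        res = dl_pool(make_estimates([0.5] * 4, [0.1] * 4))
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.tau2 == 0.0
        assert res.pooled_effect == pytest.approx(0.5)
        se = (res.ci95[1] - res.pooled_effect) / 1.96
        assert se == pytest.approx(np.sqrt(0.1 / 4), rel=1e-9)

    def test_log_or_results_exponentiate(self):
        res = dl_pool(make_estimates([0.0, 0.2], [0.1, 0.1], scale="log_or"))
        assert res.pooled_ratio == pytest.approx(np.exp(res.pooled_effect))
        lo, hi = res.ci95_ratio
        assert lo < res.pooled_ratio < hi

    def test_mixed_comparisons_rejected(self):
        a = est(0.1, 0.1)
        b = ContrastEstimate("S2", ("C100BID", "PBO"), 0.2, 0.1, "smd")
        with pytest.raises(ValueError, match="mixed comparisons"):
            dl_pool([a, b])

    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.01, 1)),
                    min_size=2, max_size=12))
    @settings(derandomize=True, deadline=None, max_examples=80)
    def test_dl_invariants(self, pairs):
        ys, vs = zip(*pairs)
        res = dl_pool(make_estimates(ys, vs))
        assert min(ys) - 1e-9 <= res.pooled_effect <= max(ys) + 1e-9
        assert res.df == len(ys) - 1
        assert 0 <= res.I2 <= 100
        if res.Q <= res.df:
            # moment estimator truncates at zero -> fixed-effect answer
            assert res.tau2 == 0.0
            w = 1 / np.array(vs)
            fe = np.sum(w * np.array(ys)) / np.sum(w)
            assert res.pooled_effect == pytest.approx(fe, rel=1e-9, abs=1e-12)

    def test_agrees_with_statsmodels_dl(self):
        # independent route: statsmodels combine_effects with DL tau^2
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(3)
        ys = rng.normal(0.2, 0.4, size=9)
        vs = rng.uniform(0.02, 0.3, size=9)
        ours = dl_pool(make_estimates(ys, vs))
        ref = combine_effects(ys, vs, method_re="dl")
        assert ours.tau2 == pytest.approx(ref.tau2, rel=1e-9)
        assert ours.Q == pytest.approx(ref.q, rel=1e-9)
        frame = ref.summary_frame()
        assert ours.pooled_effect == pytest.approx(
            frame.loc["random effect", "eff"], rel=1e-9)
        assert ours.I2 == pytest.approx(100 * max(0.0, ref.i2), abs=1e-6)

    def test_q_test_nominal_size_under_null(self):
        # true tau2 = 0 with known variances: P(p_Q <= 0.05) ~ 5%
        rng = np.random.default_rng(7)
        k, reps = 8, 2000
        rejections = 0
        for _ in range(reps):
            v = rng.uniform(0.02, 0.2, size=k)
            y = rng.normal(0.0, np.sqrt(v))
            res = dl_pool(make_estimates(y, v))
            rejections += res.p_Q <= 0.05
        assert abs(rejections / reps - 0.05) < 0.02


class TestBeggsTest:
    def test_perfect_concordance(self):
        # deviates engineered to increase with variance
        vs = np.linspace(0.05, 0.5, 10)
        ys = np.sqrt(vs) * np.linspace(0.5, 3.0, 10)
        res = beggs_test(make_estimates(ys, vs))
        assert res.kendall_tau > 0.7
        assert res.p < 0.05

    def test_insufficient_studies_flagged(self):
        res = beggs_test(make_estimates([0.1, 0.2], [0.1, 0.1]))
        assert res.insufficient and res.p == 1.0

    def test_null_level_held_and_p_roughly_uniform(self):
        # independent deviates and variances: p approximately U(0,1); the
        # continuity-corrected rank test is known to be mildly conservative,
        # so the nominal level must be held but not exceeded
        rng = np.random.default_rng(11)
        k, reps = 40, 2000
        ps = np.empty(reps)
        for i in range(reps):
            v = rng.uniform(0.02, 0.3, size=k)
            y = rng.normal(0.0, np.sqrt(v))
            ps[i] = beggs_test(make_estimates(y, v)).p
        assert 0.01 <= np.mean(ps <= 0.05) <= 0.05 + 0.02
        assert stats.kstest(ps, "uniform").statistic < 0.08
        assert 0.4 < np.median(ps) < 0.6
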