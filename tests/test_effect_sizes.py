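"""Hedges' g, log odds ratios, and the outcome-hierarchy rule."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from dosenma.effect_sizes import (
    DegenerateDataError,
    OutcomeHierarchy,
    default_hierarchy,
    hedges_g,
    log_odds_ratio,
    select_outcome,
)

from conftest import bin_arm, cont_arm


class TestHedgesG:
    def test_worked_example(self):
        # n=100 each, means 1 vs 2, common SD 2: d = -0.5, J = 1 - 3/791
        g = hedges_g(cont_arm("S", "C200QD", 100, 1.0, 2.0),
                     cont_arm("S", "PBO", 100, 2.0, 2.0))
        assert g.effect == pytest.approx(-0.5 * (1 - 3 / 791), rel=1e-12)
        assert g.effect == pytest.approx(-0.49810, abs=5e-6)
        assert g.variance == pytest.approx(
            200 / 10000 + g.effect ** 2 / 400, rel=1e-12)
        assert g.variance == pytest.approx(0.02062, abs=5e-6)

    def test_identical_arms_give_zero(self):
        g = hedges_g(cont_arm("S", "C200QD", 50, 3.0, 1.5),
                     cont_arm("S", "PBO", 70, 3.0, 1.5))
        assert g.effect == 0.0
        assert g.variance == pytest.approx((50 + 70) / (50 * 70))

    def test_zero_pooled_sd_is_degenerate(self):
        a = cont_arm("S", "C200QD", 1, 1.0, 1.0)  # df weight 0 at n=1
        b = cont_arm("S", "PBO", 2, 2.0, 1e-300)
        with pytest.raises(DegenerateDataError):
            hedges_g(a, b)

    def test_requires_same_study(self):
        with pytest.raises(ValueError, match="same study"):
            hedges_g(cont_arm("S1", "C200QD", 10, 1, 1),
                     cont_arm("S2", "PBO", 10, 1, 1))

    @given(n1=st.integers(2, 400), n2=st.integers(2, 400),
           m1=st.floats(-5, 5), m2=st.floats(-5, 5),
           s1=st.floats(0.1, 5), s2=st.floats(0.1, 5))
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_antisymmetry_and_shrinkage(self, n1, n2, m1, m2, s1, s2):
        x = cont_arm("S", "C200QD", n1, m1, s1)
        y = cont_arm("S", "PBO", n2, m2, s2)
        g_xy = hedges_g(x, y)
        g_yx = hedges_g(y, x)
        assert g_xy.effect == pytest.approx(-g_yx.effect, abs=1e-12)
        assert g_xy.variance == pytest.approx(g_yx.variance, rel=1e-12)
        # |g| <= |d| since J < 1
        df = n1 + n2 - 2
        sp = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df)
        assert abs(g_xy.effect) <= abs((m1 - m2) / sp) + 1e-12

    def test_variance_decreases_with_sample_size(self):
        base = dict(mean=1.0, sd=2.0)
        small = hedges_g(cont_arm("S", "A", 20, **base),
                         cont_arm("S", "B", 20, 2.0, 2.0))
        large = hedges_g(cont_arm("S", "A", 200, **base),
                         cont_arm("S", "B", 200, 2.0, 2.0))
        assert large.variance < small.variance


class TestLogOddsRatio:
    def test_symmetric_table_is_null(self):
        est = log_odds_ratio(bin_arm("S", "C200QD", 100, 10),
                             bin_arm("S", "PBO", 100, 10))
        assert est.effect == 0.0
        assert est.variance == pytest.approx(2 * (1 / 10 + 1 / 90))

    def test_worked_example(self):
        est = log_odds_ratio(bin_arm("S", "C200QD", 100, 20),
                             bin_arm("S", "PBO", 100, 10))
        assert math.exp(est.effect) == pytest.approx(2.25, rel=1e-12)
        assert est.effect == pytest.approx(0.8109, abs=5e-5)
        assert est.variance == pytest.approx(
            1 / 20 + 1 / 80 + 1 / 10 + 1 / 90, rel=1e-12)
        assert est.variance == pytest.approx(0.17361, abs=5e-6)

    def test_zero_cell_gets_haldane_correction(self):
        est = log_odds_ratio(bin_arm("S", "C200QD", 50, 0),
                             bin_arm("S", "PBO", 50, 5))
        expected = math.log((0.5 * 45.5) / (50.5 * 5.5))
        assert est.effect == pytest.approx(expected, rel=1e-12)
        assert est.variance == pytest.approx(
            1 / 0.5 + 1 / 50.5 + 1 / 5.5 + 1 / 45.5, rel=1e-12)
        assert not est.double_zero

    def test_double_zero_flagged_but_finite(self):
        est = log_odds_ratio(bin_arm("S", "A", 50, 0), bin_arm("S", "B", 60, 0))
        assert est.double_zero
        assert math.isfinite(est.effect) and math.isfinite(est.variance)

    @given(n1=st.integers(2, 300), n2=st.integers(2, 300), data=st.data())
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_antisymmetry(self, n1, n2, data):
        e1 = data.draw(st.integers(0, n1))
        e2 = data.draw(st.integers(0, n2))
        x, y = bin_arm("S", "A", n1, e1), bin_arm("S", "B", n2, e2)
        assert log_odds_ratio(x, y).effect == pytest.approx(
            -log_odds_ratio(y, x).effect, abs=1e-12)
        assert log_odds_ratio(x, y).variance == pytest.approx(
            log_odds_ratio(y, x).variance, rel=1e-12)


class TestOutcomeHierarchy:
    def test_function_hierarchy_prefers_womac_function(self):
        h = default_hierarchy("function")
        chosen = select_outcome(
            [("WOMAC_total", "total"), ("WOMAC_function", "function")], h)
        assert chosen == "function"

    def test_womac_total_beats_lequesne(self):
        h = default_hierarchy("function")
        assert select_outcome(
            [("Lequesne", "leq"), ("WOMAC_total", "tot")], h) == "tot"

    def test_single_candidate_returned(self):
        h = OutcomeHierarchy(("A", "B"))
        assert select_outcome([("B", 42)], h) == 42

    def test_no_match_is_an_error(self):
        h = OutcomeHierarchy(("A",))
        with pytest.raises(ValueError, match="hierarchy"):
            select_outcome([("Z", 1)], h)

    def test_duplicate_scales_rejected(self):
        with pytest.raises(ValueError):
            OutcomeHierarchy(("A", "A"))

    def test_pain_hierarchy_order(self):
        h = default_hierarchy("pain")
        assert h.rank("VAS_walking") < h.rank("WOMAC_pain") < h.rank("other")
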