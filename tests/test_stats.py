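"""Group-comparison statistics against independent hand/enumeration oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from epimech.stats import (GroupSample, compare_groups, mann_whitney_u,
                           one_way_anova, percent_change, significance_stars,
                           students_t, summarize)


def gs(label, values):
    return GroupSample(label=label, values=np.asarray(values, dtype=float))


def enumeration_mw(x, y):
    """Brute-force exact Mann-Whitney oracle: full relabelling enumeration."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array([ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
                   for idx in combinations(range(len(pooled)), n1)])
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return u_obs, min(1.0, p)


class TestMannWhitney:
    def test_fully_separated_pairs_worked_example(self):
        u, p = mann_whitney_u(gs("x", [1, 2]), gs("y", [3, 4]))
        assert u == 0.0
        assert abs(p - 2 / 6) < 1e-12

    def test_identical_samples_give_p_one(self):
        u, p = mann_whitney_u(gs("x", [2, 2, 2]), gs("y", [2, 2]))
        assert p == 1.0

    def test_two_sided_p_symmetric_under_swap(self, rng):
        x, y = rng.normal(size=6), rng.normal(1.0, size=5)
        _, p_xy = mann_whitney_u(gs("x", x), gs("y", y))
        _, p_yx = mann_whitney_u(gs("y", y), gs("x", x))
        assert abs(p_xy - p_yx) < 1e-12

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_p_matches_enumeration_for_small_tie_free_samples(self, data):
        n1 = data.draw(st.integers(2, 5))
        n2 = data.draw(st.integers(2, min(5, 10 - n1)))
        vals = data.draw(st.lists(
            st.floats(-100, 100, allow_nan=False).map(lambda v: round(v, 3)),
            min_size=n1 + n2, max_size=n1 + n2, unique=True))
        x, y = vals[:n1], vals[n1:]
        u, p = mann_whitney_u(gs("x", x), gs("y", y))
        u_ref, p_ref = enumeration_mw(x, y)
        assert abs(p - p_ref) < 1e-10

    def test_large_samples_use_corrected_normal_approximation(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(1.2, size=18)
        _, p = mann_whitney_u(gs("x", x), gs("y", y))
        assert 0 < p < 1


class TestStudentsT:
    def test_textbook_pooled_variance_example(self):
        t, p = students_t(gs("x", [1, 2, 3]), gs("y", [3, 4, 5]))
        assert abs(t - (-2.449489742783178)) < 1e-9   # -2 / sqrt(2/3)
        assert abs(p - 0.07048399691021557) < 1e-6    # df = 4

    def test_equal_samples_give_zero_t(self):
        t, p = students_t(gs("x", [1, 2, 3]), gs("y", [1, 2, 3]))
        assert t == 0.0 and abs(p - 1.0) < 1e-12

    def test_scale_equivariance(self):
        t1, _ = students_t(gs("x", [1, 2, 3]), gs("y", [4, 5, 7]))
        t2, _ = students_t(gs("x", [10, 20, 30]), gs("y", [40, 50, 70]))
        assert abs(t1 - t2) < 1e-9

    def test_degenerate_constant_samples(self):
        assert students_t(gs("x", [2, 2]), gs("y", [2, 2])) == (0.0, 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            students_t(gs("x", [2, 2]), gs("y", [3, 3]))


class TestAnova:
    def test_hand_decomposed_three_group_example(self):
        # SSB = 42, SSW = 6 -> F = (42/2)/(6/6) = 21; p = 1/512 for F(2, 6)
        F, p = one_way_anova([gs("a", [1, 2, 3]), gs("b", [2, 3, 4]),
                              gs("c", [6, 7, 8])])
        assert abs(F - 21.0) < 1e-9
        assert abs(p - 1 / 512) < 1e-9

    def test_identical_groups_give_zero_f(self):
        F, p = one_way_anova([gs("a", [1, 2, 3]), gs("b", [1, 2, 3])])
        assert F == 0.0 or abs(F) < 1e-12
        assert abs(p - 1.0) < 1e-9

    def test_two_groups_f_equals_t_squared(self, rng):
        x, y = rng.normal(size=8), rng.normal(0.5, size=6)
        F, p_f = one_way_anova([gs("x", x), gs("y", y)])
        t, p_t = students_t(gs("x", x), gs("y", y))
        assert abs(F - t ** 2) < 1e-9
        assert abs(p_f - p_t) < 1e-9

    def test_degenerate_zero_within_variance(self):
        with pytest.raises(ValueError, match="degenerate"):
            one_way_anova([gs("a", [1, 1]), gs("b", [2, 2])])


class TestPercentChangeAndSummary:
    def test_equal_means_give_zero(self):
        assert percent_change(gs("t", [2, 4]), gs("c", [3, 3])) == 0.0

    @pytest.mark.parametrize("treated_mean,expected", [(0.051, -49.0),
                                                       (0.143, 43.0)])
    def test_reporting_convention_examples(self, treated_mean, expected):
        pc = percent_change(gs("t", [treated_mean]), gs("c", [0.100]))
        assert abs(pc - expected) < 1e-9

    def test_multiplicative_effect_antisymmetry(self):
        # effect c on treated gives 100*(c-1); inverting roles gives 100*(1/c-1)
        c = 1.37
        base = gs("c", [1.0, 2.0, 3.0])
        scaled = gs("t", [c * v for v in (1.0, 2.0, 3.0)])
        assert abs(percent_change(scaled, base) - 100 * (c - 1)) < 1e-9
        assert abs(percent_change(base, scaled) - 100 * (1 / c - 1)) < 1e-9

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError, match="control"):
            percent_change(gs("t", [1.0, 2.0]), gs("c", [-1.0, 1.0]))

    def test_summary_uses_sample_sd(self):
        s = summarize(gs("a", [1, 2, 3, 4]))
        assert s.mean == 2.5 and abs(s.sd - 1.2909944487358056) < 1e-12
        assert s.n == 4

    def test_single_observation_sd_flagged_nan(self):
        s = summarize(gs("a", [5.0]))
        assert s.mean == 5.0 and np.isnan(s.sd) and s.n == 1

    def test_constant_sample_sd_zero(self):
        assert summarize(gs("a", [3, 3, 3])).sd == 0.0


class TestComparisonReport:
    def test_stars_thresholds(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.00009) == "****"

    def test_full_report_fields(self, rng):
        c = gs("control", rng.normal(0.10, 0.01, size=17))
        t = gs("knockdown", rng.normal(0.051, 0.01, size=12))
        cmp = compare_groups(c, t, test="mann-whitney")
        assert cmp.ns == (17, 12)
        assert cmp.test_name.startswith("Mann-Whitney")
        assert cmp.percent_change < -30
        assert 0 < cmp.p_value <= 1
        assert not cmp.degenerate
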