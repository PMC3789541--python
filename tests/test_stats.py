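"""Regression, Mann–Whitney U, p-value adjustment and the plugin registry."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from woundkit.dataio import TimeSeries
from woundkit.errors import ConflictError, ValidationError
from woundkit.plate import WellAddress
from woundkit.plugins import PluginRegistry
from woundkit.preprocessing import normalize, orient
from woundkit.stats import (
    adjust_pvalues,
    compare_conditions,
    condition_velocity,
    fit_replicate,
    mann_whitney_u,
)

A1 = WellAddress(1, 1)


def ns_from(values, times=None, well=A1):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values), dtype=float) if times is None else np.asarray(times, float)
    return orient(normalize(TimeSeries(well, "d", t, values)), "open_area")


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------


class TestFitReplicate:
    def test_exact_line(self):
        fit = fit_replicate(ns_from([100, 90, 80]))
        assert fit.slope == pytest.approx(-10.0)
        assert fit.intercept == pytest.approx(100.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_series_zero_variance_rule(self):
        fit = fit_replicate(ns_from([100, 100, 100, 100]))
        assert fit.slope == 0.0
        assert fit.r_squared == 1.0

    def test_hand_computed_ols(self):
        # t=[0,1,2], y=[100,95,84]: slope = -16/2 = -8, intercept = 101,
        # SSres = 6, SStot = 134 -> R^2 = 1 - 6/134
        fit = fit_replicate(ns_from([100, 95, 84]))
        assert fit.slope == pytest.approx(-8.0)
        assert fit.intercept == pytest.approx(101.0)
        assert fit.r_squared == pytest.approx(1 - 6 / 134)

    @given(
        st.lists(st.floats(10, 1000), min_size=3, max_size=25),
    )
    def test_matches_scipy_linregress(self, areas):
        ns = ns_from(areas)
        if np.allclose(ns.normalized, ns.normalized[0]):
            return
        fit = fit_replicate(ns)
        ref = sps.linregress(ns.time, ns.normalized)
        assert fit.slope == pytest.approx(ref.slope, rel=1e-9, abs=1e-9)
        assert fit.intercept == pytest.approx(ref.intercept, rel=1e-9, abs=1e-9)
        assert fit.r_squared == pytest.approx(ref.rvalue**2, rel=1e-7, abs=1e-9)

    @given(
        st.floats(-12, -1),
        st.floats(0.5, 3.0),
        st.floats(1.0, 10.0),
    )
    def test_r_squared_invariant_under_affine_rescaling(self, slope, tscale, yscale):
        rng = np.random.default_rng(5)
        t = np.arange(8.0)
        y = 100 + slope * t + rng.normal(0, 1.0, 8)
        y = np.maximum(y, 1.0)
        base = fit_replicate(ns_from(y, times=t))
        scaled_t = fit_replicate(ns_from(y, times=t * tscale))
        assert scaled_t.r_squared == pytest.approx(base.r_squared, rel=1e-9)
        # rescaling areas before normalization cancels entirely
        scaled_y = fit_replicate(ns_from(y * yscale, times=t))
        assert scaled_y.r_squared == pytest.approx(base.r_squared, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_replicate(ns_from([100, 90]))


class TestConditionVelocity:
    @pytest.mark.parametrize(
        "slopes,expected",
        [([-8, -10, -12], -10.0), ([-8, -10], -9.0), ([-10], -10.0)],
    )
    def test_median_rules(self, slopes, expected):
        fits = [fit_replicate(ns_from(100 + np.array(s) * np.arange(3.0))) for s in slopes]
        assert condition_velocity("c", fits).median_velocity == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            condition_velocity("c", [])


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def oracle_mwu_exact(a, b):
    """Brute-force: U by direct pairwise counting, p by full enumeration."""
    a, b = list(a), list(b)

    def u_of(x, y):
        return sum(
            (1.0 if xi > yi else 0.5 if xi == yi else 0.0) for xi in x for yi in y
        )

    u_obs = u_of(a, b)
    pooled = a + b
    n, n_a = len(pooled), len(a)
    u_min = min(u_obs, len(a) * len(b) - u_obs)
    count = total = 0
    for idx in combinations(range(n), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        total += 1
        if u_of(ga, gb) <= u_min + 1e-12:
            count += 1
    return u_obs, min(1.0, 2.0 * count / total)


class TestMannWhitney:
    def test_extreme_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * (1/20)

    def test_identical_samples(self):
        u, p = mann_whitney_u([5, 5], [5, 5], mode="exact")
        assert u == 2.0  # n_a * n_b / 2
        assert p == 1.0

    def test_interleaved_matches_oracle(self):
        u, p = mann_whitney_u([1, 3, 5], [2, 4, 6], mode="exact")
        uo, po = oracle_mwu_exact([1, 3, 5], [2, 4, 6])
        assert u == uo
        assert p == pytest.approx(po, abs=1e-12)

    @given(st.data())
    def test_exact_agrees_with_enumeration_oracle(self, data):
        n_a = data.draw(st.integers(1, 5))
        n_b = data.draw(st.integers(1, 9 - n_a))
        vals = data.draw(
            st.lists(
                st.integers(0, 100),
                min_size=n_a + n_b,
                max_size=n_a + n_b,
                unique=True,
            )
        )
        a, b = vals[:n_a], vals[n_a:]
        u, p = mann_whitney_u(a, b, mode="exact")
        uo, po = oracle_mwu_exact(a, b)
        assert u == pytest.approx(uo)
        assert p == pytest.approx(po, abs=1e-12)

    @given(st.data())
    def test_u_complement_identity(self, data):
        a = data.draw(st.lists(st.floats(-10, 10), min_size=1, max_size=8))
        b = data.draw(st.lists(st.floats(-10, 10), min_size=1, max_size=8))
        u_ab, _ = mann_whitney_u(a, b, mode="normal_approx")
        u_ba, _ = mann_whitney_u(b, a, mode="normal_approx")
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_exact_matches_scipy(self):
        a, b = [1.2, 3.4, 2.2, 5.1], [4.4, 6.2, 7.0, 3.9]
        u, p = mann_whitney_u(a, b, mode="exact")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.8, 1, 25)
        u, p = mann_whitney_u(a, b, mode="normal_approx")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_use_midranks_and_corrected_variance(self):
        a = [1, 2, 2, 3, 5, 5]
        b = [2, 2, 4, 5, 6, 6]
        u, p = mann_whitney_u(a, b, mode="normal_approx")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------


def oracle_bh(p):
    """Literal step-up recursion: q_(i) = min_{j: rank(j) >= rank(i)} m p_(j) / rank(j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    return np.array(
        [
            min(min(1.0, m * p[j] / ranks[j]) for j in range(m) if ranks[j] >= ranks[i])
            for i in range(m)
        ]
    )


class TestAdjustPvalues:
    def test_bonferroni_hand_values(self):
        assert np.allclose(adjust_pvalues([0.01, 0.04], "bonferroni"), [0.02, 0.08])

    def test_bh_hand_values(self):
        # all four raw p reach the same step-up value 0.04
        got = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "benjamini_hochberg")
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity(self):
        for method in ("bonferroni", "benjamini_hochberg"):
            assert adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    @given(st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=25))
    def test_bh_matches_bruteforce_and_statsmodels(self, p):
        got = adjust_pvalues(p, "benjamini_hochberg")
        assert np.allclose(got, oracle_bh(p), atol=1e-12)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(got, ref, atol=1e-12)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=25))
    def test_bonferroni_dominates_bh(self, p):
        bonf = adjust_pvalues(p, "bonferroni")
        bh = adjust_pvalues(p, "benjamini_hochberg")
        assert np.all(bonf >= bh - 1e-15)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=12), st.randoms())
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        shuffled = [p[i] for i in perm]
        base = adjust_pvalues(p, "benjamini_hochberg")
        assert np.allclose(
            adjust_pvalues(shuffled, "benjamini_hochberg"), [base[i] for i in perm]
        )

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [-0.1]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            adjust_pvalues(bad, "bonferroni")


# ---------------------------------------------------------------------------
# Pairwise comparisons + plugins
# ---------------------------------------------------------------------------


def result_with_slopes(name, slopes):
    fits = [
        fit_replicate(ns_from(100 + s * np.arange(4.0), well=WellAddress(1, i + 1)))
        for i, s in enumerate(slopes)
    ]
    return condition_velocity(name, fits)


class TestCompareConditions:
    def test_three_conditions_give_three_pairs(self):
        results = [
            result_with_slopes("a", [-10, -11, -9]),
            result_with_slopes("b", [-5, -6, -4]),
            result_with_slopes("c", [-1, -2, -3]),
        ]
        comps = compare_conditions(results, method="bonferroni")
        assert len(comps) == 3

    def test_identical_conditions_not_significant(self):
        results = [
            result_with_slopes("a", [-5, -6, -4]),
            result_with_slopes("b", [-5, -6, -4]),
        ]
        (c,) = compare_conditions(results)
        assert c.p_adjusted == 1.0
        assert not c.significant

    def test_bonferroni_multiplicity_is_pair_count(self):
        results = [
            result_with_slopes("a", [-10, -11, -9, -10.5]),
            result_with_slopes("b", [-1, -2, -1.5, -2.5]),
            result_with_slopes("c", [-1.1, -2.2, -1.4, -2.6]),
        ]
        comps = compare_conditions(results, method="bonferroni")
        for c in comps:
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * c.p_raw))

    def test_unknown_selection_raises(self):
        results = [result_with_slopes("a", [-1, -2, -3])]
        with pytest.raises(LookupError):
            compare_conditions(results, selection=["a", "zz"])


class TestPluginRegistry:
    def test_register_and_retrieve(self):
        reg = PluginRegistry()
        fn = lambda x, y: 0.0
        reg.register("distance_metric", "null", fn)
        assert reg.get("distance_metric", "null") is fn
        assert "null" in reg.available("distance_metric")

    def test_duplicate_name_conflicts(self):
        reg = PluginRegistry()
        reg.register("distance_metric", "euclidean", lambda x, y: 0.0)
        with pytest.raises(ConflictError):
            reg.register("distance_metric", "euclidean", lambda x, y: 1.0)

    def test_unknown_slot_raises(self):
        with pytest.raises(LookupError):
            PluginRegistry().register("frobnicator", "x", lambda: None)

    def test_default_registry_has_all_slots_filled(self):
        from woundkit.plugins import SLOTS, registry

        defaults = {
            "distance_metric": "euclidean",
            "statistical_test": "mann_whitney",
            "kde_kernel": "gaussian",
            "outlier_rule": "central_mass",
            "correction_method": "benjamini_hochberg",
        }
        for slot in SLOTS:
            assert registry.get(slot, defaults[slot]) is not None

    def test_registered_metric_usable_in_qc(self):
        from woundkit.plugins import registry
        from woundkit.qc import replicate_distances

        if "chebyshev" not in registry.available("distance_metric"):
            registry.register(
                "distance_metric",
                "chebyshev",
                lambda x, y: float(np.max(np.abs(x - y))),
            )
        a = ns_from([100, 90, 80], well=WellAddress(1, 1))
        b = ns_from([100, 86, 77], well=WellAddress(1, 2))
        rep = replicate_distances([a, b], metric="chebyshev")
        assert rep.distance_matrix[0, 1] == pytest.approx(4.0)
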