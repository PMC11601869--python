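"""Dip statistic/test, Kaplan-Meier, log-rank, Fisher, age densities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import dip_lp, km_bruteforce

from cycleage import (
    age_density,
    dip_statistic,
    dip_test,
    fisher_exact,
    km_estimate,
    logrank_test,
)
from cycleage.exceptions import ComputationError, InputError


class TestDipStatistic:
    def test_two_point_sample(self):
        assert dip_statistic([0.0, 1.0]) == pytest.approx(0.25, abs=1e-12)

    def test_equally_spaced_four_points(self):
        assert dip_statistic([0.0, 1.0, 2.0, 3.0]) == pytest.approx(0.125, abs=1e-12)

    def test_point_mass_is_perfectly_unimodal(self):
        assert dip_statistic([2.0, 2.0, 2.0]) == 0.0

    def test_matches_lp_oracle_on_random_samples(self, rng):
        for trial in range(120):
            n = int(rng.integers(2, 26))
            kind = trial % 3
            if kind == 0:
                x = rng.normal(size=n)
            elif kind == 1:
                x = np.concatenate([rng.normal(-3, 0.5, n // 2 + 1), rng.normal(3, 0.5, n // 2 + 1)])
            else:
                x = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            assert dip_statistic(x) == pytest.approx(dip_lp(x), abs=1e-9)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=40,
            unique=True,
        )
    )
    def test_bounds_for_distinct_samples(self, xs):
        n = len(xs)
        d = dip_statistic(xs)
        assert 1 / (2 * n) - 1e-12 <= d <= 0.25 + 1e-12

    def test_rejects_tiny_or_nonfinite_input(self):
        with pytest.raises(InputError):
            dip_statistic([1.0])
        with pytest.raises(InputError):
            dip_statistic([1.0, np.nan])


class TestDipTest:
    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=50)
        a = dip_test(x, n_boot=199, seed=42)
        b = dip_test(x, n_boot=199, seed=42)
        assert a.p == b.p and a.dip == b.dip

    def test_bimodal_mixture_rejected_unimodal_not(self):
        r = np.random.default_rng(7)
        bim = np.concatenate([r.normal(45, 3, 150), r.normal(65, 3, 150)])
        uni = r.normal(55, 8, 300)
        assert dip_test(bim, n_boot=499, seed=1).p < 0.01
        assert dip_test(uni, n_boot=499, seed=1).p > 0.05

    def test_warnings_on_small_inputs(self):
        with pytest.warns(UserWarning, match="n_boot"):
            dip_test([1.0, 2.0, 3.0, 4.0, 2.5], n_boot=50, seed=0)


class TestKaplanMeier:
    def test_all_events_hand_example(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_censored_hand_example(self):
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)
        np.testing.assert_allclose(km.times, [1.0, 3.0])

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([5, 6, 7], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(100) == 1.0

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        t = rng.exponential(10, size=80)
        km = km_estimate(t, np.ones_like(t))
        for et, s in zip(km.times, km.survival):
            assert s == pytest.approx(1 - (t <= et).mean(), abs=1e-12)

    def test_matches_subjectwise_bruteforce_with_ties(self, rng):
        t = rng.integers(1, 10, size=60).astype(float)
        e = rng.integers(0, 2, size=60)
        km = km_estimate(t, e)
        oracle = km_bruteforce(t, e)
        for et, s in zip(km.times, km.survival):
            assert s == pytest.approx(oracle[et], abs=1e-12)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(8, size=100)
        e = rng.integers(0, 2, size=100)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        km = km_estimate(t, e)
        for et, s in zip(km.times, km.survival):
            assert s == pytest.approx(kmf.predict(et), abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(InputError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        res = logrank_test(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_enumerated_separated_groups(self):
        # A: 3 events at t=1; B: 3 events at t=2
        # t=1: r=6, d=3, rA=3 -> E_A = 1.5, V = 3*3*3*3/(36*5) = 0.45
        # t=2: r=3 (all B), d=3, rA=0 -> E_A = 0, V = 0
        # chi2 = (3-1.5)^2 / 0.45 = 5.0
        res = logrank_test([1, 1, 1], [1, 1, 1], [2, 2, 2], [1, 1, 1])
        assert res.chi_square == pytest.approx(5.0, abs=1e-12)

    def test_symmetric_in_group_labels(self, rng):
        ta, tb = rng.exponential(5, 40), rng.exponential(8, 50)
        ea, eb = rng.integers(0, 2, 40), rng.integers(0, 2, 50)
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-10)
        assert r1.chi_square >= 0

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank

        ta, tb = rng.exponential(5, 60), rng.exponential(9, 45)
        ea, eb = rng.integers(0, 2, 60), rng.integers(0, 2, 45)
        ours = logrank_test(ta, ea, tb, eb)
        theirs = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert ours.chi_square == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert ours.p == pytest.approx(theirs.p_value, rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ComputationError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_enumeration_examples(self):
        assert fisher_exact([[3, 1], [1, 3]]) == pytest.approx(34 / 70, rel=1e-9)
        assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(2 / 184756, rel=1e-9)

    def test_transpose_symmetry(self, rng):
        for _ in range(25):
            t = rng.integers(0, 12, size=(2, 2))
            if 0 in (*t.sum(0), *t.sum(1)):
                continue
            assert fisher_exact(t) == pytest.approx(fisher_exact(t.T), rel=1e-9)

    def test_matches_scipy(self, rng):
        from scipy.stats import fisher_exact as scipy_fisher

        for _ in range(25):
            t = rng.integers(0, 15, size=(2, 2))
            if 0 in (*t.sum(0), *t.sum(1)):
                continue
            assert fisher_exact(t) == pytest.approx(scipy_fisher(t)[1], rel=1e-8)

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="margin"):
            assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    def test_doubling_rule_flag(self):
        from scipy.stats import hypergeom

        a, b, c, d = 8, 2, 3, 9
        lower = hypergeom.cdf(a, a + b + c + d, a + c, a + b)
        upper = hypergeom.sf(a - 1, a + b + c + d, a + c, a + b)
        expected = min(1.0, 2 * min(lower, upper))
        assert fisher_exact([[a, b], [c, d]], method="double") == pytest.approx(
            expected, rel=1e-9
        )


class TestAgeDensity:
    def test_densities_integrate_to_one(self, rng):
        ages = np.concatenate([rng.normal(45, 3, 100), rng.normal(65, 3, 100)])
        groups = np.array(["high"] * 100 + ["low"] * 100)
        out = age_density(ages, groups)
        dens = out["density"]
        for g in ("high", "low"):
            area = np.trapezoid(dens[g], dens["age"])
            assert area == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_ages_give_two_kde_modes(self, rng):
        ages = np.concatenate([rng.normal(45, 3, 200), rng.normal(65, 3, 200)])
        out = age_density(ages)
        y = out["density"]["all"].to_numpy()
        interior = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
        assert interior.sum() == 2

    def test_identical_ages_single_bin(self):
        out = age_density([50.0, 50.0, 50.0])
        hist = out["hist"]
        assert (hist.density > 0).sum() == 1

    def test_tiny_group_rejected(self):
        with pytest.raises(InputError):
            age_density([50.0, 60.0], ["a", "b"])
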