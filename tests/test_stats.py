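"""Correlation, fold-change and bootstrap statistics against oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from coregulation import (
    InteractionSet,
    ParamsTable,
    PairedValues,
    bootstrap_difference_ci,
    bootstrap_statistic_ci,
    correlation_difference_ci,
    fold_changes,
    log_fold_changes,
    pair_values,
    spearman_with_ci,
)
from oracles import (
    brute_spearman,
    lognormal_pair_targets,
    median_fold_change_mc_se,
    sd_mc_se,
    spearman_of_bivariate_normal,
)


def pv(first, second, parameter="R"):
    n = len(first)
    ids = tuple((f"A{i}", f"B{i}") for i in range(n))
    return PairedValues(parameter, np.asarray(first, float),
                        np.asarray(second, float), ids)


class TestPairValues:
    @pytest.fixture
    def setting(self):
        table = ParamsTable(pd.DataFrame(
            {"R": [1.0, 2.0, 3.0, 4.0]}, index=["P1", "P2", "P3", "P4"]))
        edges = InteractionSet.from_pairs([("P1", "P2"), ("P3", "P4")], "binary")
        return table, edges

    def test_as_loaded_follows_canonical_order(self, setting):
        table, edges = setting
        out = pair_values(edges, table, "R", order_policy="as-loaded")
        assert list(out.first) == [1.0, 3.0]
        assert list(out.second) == [2.0, 4.0]

    def test_randomized_deterministic_given_seed(self, setting):
        table, edges = setting
        a = pair_values(edges, table, "R", seed=5)
        b = pair_values(edges, table, "R", seed=5)
        np.testing.assert_array_equal(a.first, b.first)

    def test_randomized_orientation_is_fair_coin(self):
        n = 10_000
        genes = [f"P{i}" for i in range(2 * n)]
        table = ParamsTable(pd.DataFrame(
            {"R": np.arange(1.0, 2 * n + 1)}, index=genes))
        edges = InteractionSet.from_pairs(
            [(genes[2 * i], genes[2 * i + 1]) for i in range(n)], "t")
        out = pair_values(edges, table, "R", seed=3)
        frac = np.mean(out.first < out.second)
        assert abs(frac - 0.5) < 0.015  # 3 sigma of a fair binomial

    def test_absent_value_is_hard_error(self):
        table = ParamsTable(pd.DataFrame({"R": [1.0, np.nan]}, index=["P1", "P2"]))
        edges = InteractionSet.from_pairs([("P1", "P2")], "t")
        with pytest.raises(ValueError, match="restrict_to_analyzable"):
            pair_values(edges, table, "R")


class TestSpearman:
    def test_monotone_couples_give_one(self):
        x = np.arange(10.0)
        assert spearman_with_ci(pv(x, x**3 + 1)).rho == pytest.approx(1.0, abs=1e-12)

    def test_antitone_couples_give_minus_one(self):
        x = np.arange(10.0) + 1
        assert spearman_with_ci(pv(x, -x)).rho == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_rank_formula(self):
        # ranks identical to values; sum d^2 = 4 -> 1 - 24/120 = 0.8
        est = spearman_with_ci(pv([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]))
        assert est.rho == pytest.approx(0.8, abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(4, 12), st.integers(0, 10_000))
    def test_matches_brute_force_with_ties(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, n).astype(float)
        y = rng.integers(0, 4, n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        est = spearman_with_ci(pv(x, y))
        assert est.rho == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r1 = spearman_with_ci(pv(x, y)).rho
        r2 = spearman_with_ci(pv(np.exp(x), y)).rho
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_small_sample_and_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            spearman_with_ci(pv([1, 2, 3], [1, 2, 3]))
        with pytest.raises(ValueError, match="variance"):
            spearman_with_ci(pv([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_bonett_wright_wider_than_fisher_for_nonzero_rho(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        y = x + 0.5 * rng.normal(size=100)
        f = spearman_with_ci(pv(x, y), method="fisher")
        bw = spearman_with_ci(pv(x, y), method="bonett-wright")
        assert bw.width() > f.width()
        assert bw.rho == f.rho

    def test_bootstrap_interval_deterministic(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        a = spearman_with_ci(pv(x, y), method="bootstrap", reps=200, seed=9)
        b = spearman_with_ci(pv(x, y), method="bootstrap", reps=200, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.rho <= a.ci_high

    def test_converges_to_bivariate_normal_closed_form(self):
        """Sample Spearman of a latent bivariate normal approaches
        (6/pi)*arcsin(rho/2)."""
        rho = 0.5
        rng = np.random.default_rng(4)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=5000)
        est = spearman_with_ci(pv(z[:, 0], z[:, 1]))
        assert est.rho == pytest.approx(spearman_of_bivariate_normal(rho), abs=0.02)


class TestCorrelationDifference:
    def _estimate(self, rho, n):
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        return spearman_with_ci(pv(z[:, 0], z[:, 1]))

    def test_equal_estimates_symmetric_about_zero(self):
        e = self._estimate(0.5, 100)
        diff = correlation_difference_ci(e, e)
        assert diff.delta == 0.0
        assert diff.ci_low == pytest.approx(-diff.ci_high, abs=1e-12)
        assert diff.ci_low < 0 < diff.ci_high

    def test_small_sample_side_dominates_width(self):
        e_small = self._estimate(0.6, 50)
        e_large = self._estimate(0.6, 5000)
        diff = correlation_difference_ci(e_small, e_large)
        assert diff.ci_low < 0 < diff.ci_high
        # interval essentially reproduces the small sample's own CI geometry
        assert diff.ci_high - diff.ci_low == pytest.approx(
            e_small.ci_high - e_small.ci_low, rel=0.05)

    def test_reduces_to_single_ci_as_one_group_grows(self):
        e1 = self._estimate(0.4, 200)
        huge = self._estimate(0.4, 200)
        pinned = type(e1)(rho=huge.rho, ci_low=huge.rho, ci_high=huge.rho,
                          n=10**9, level=0.95)
        diff = correlation_difference_ci(e1, pinned)
        assert diff.ci_low == pytest.approx(e1.ci_low - pinned.rho, abs=1e-12)
        assert diff.ci_high == pytest.approx(e1.ci_high - pinned.rho, abs=1e-12)


class TestFoldChanges:
    @pytest.mark.parametrize("a,b,expected", [(2, 4, 2), (4, 2, 2), (3, 3, 1)])
    def test_larger_over_smaller(self, a, b, expected):
        assert fold_changes(pv([a], [b]))[0] == expected

    def test_orientation_invariance_exact(self):
        rng = np.random.default_rng(5)
        sample = pv(rng.lognormal(size=200), rng.lognormal(size=200))
        np.testing.assert_array_equal(
            fold_changes(sample), fold_changes(sample.flipped()))

    def test_nonpositive_value_names_pair(self):
        with pytest.raises(ValueError, match="A1"):
            fold_changes(pv([1, 0], [2, 3]))

    @pytest.mark.parametrize("a,b,expected", [(2, 4, -1), (4, 2, 1), (3, 3, 0)])
    def test_log_fold_change_base2(self, a, b, expected):
        assert log_fold_changes(pv([a], [b]), base=2)[0] == pytest.approx(expected)

    def test_log_fold_change_flip_negates(self):
        rng = np.random.default_rng(6)
        sample = pv(rng.lognormal(size=50), rng.lognormal(size=50))
        np.testing.assert_allclose(
            log_fold_changes(sample), -log_fold_changes(sample.flipped()))

    def test_iid_lognormal_closed_forms(self):
        """Median fold change -> exp(sqrt(2)*sigma*z_.75); sd of log fold
        change -> sqrt(2)*sigma, within 3 Monte-Carlo SEs at n=10000."""
        sigma, n = 0.7, 10_000
        rng = np.random.default_rng(7)
        sample = pv(rng.lognormal(0.0, sigma, n), rng.lognormal(0.0, sigma, n))
        med_target, sd_target = lognormal_pair_targets(sigma)
        med = np.median(fold_changes(sample))
        sd = np.std(log_fold_changes(sample), ddof=1)
        assert abs(med - med_target) < 3 * median_fold_change_mc_se(sigma, n)
        assert abs(sd - sd_target) < 3 * sd_mc_se(math.sqrt(2) * sigma, n)


class TestBootstrap:
    def test_constant_vector_zero_width(self):
        out = bootstrap_statistic_ci([2.0] * 10, "median", reps=100, seed=0)
        assert out.estimate == 2.0
        assert out.ci_low == out.ci_high == 2.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        values = rng.exponential(size=60)
        for method in ("normal", "percentile"):
            a = bootstrap_statistic_ci(values, "sd", reps=300, method=method, seed=4)
            b = bootstrap_statistic_ci(values, "sd", reps=300, method=method, seed=4)
            assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_sd_needs_two_observations(self):
        with pytest.raises(ValueError):
            bootstrap_statistic_ci([1.0], "sd", reps=10)

    def test_difference_null_case_contains_zero(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=200)
        out = bootstrap_difference_ci(a, a, "median", reps=500, seed=1)
        assert out.estimate == 0.0
        assert out.ci_low <= 0.0 <= out.ci_high

    def test_difference_with_disjoint_supports_excludes_zero(self):
        rng = np.random.default_rng(10)
        b = rng.normal(0.0, 0.05, size=1000)
        a = b + 1.0
        out = bootstrap_difference_ci(a, b, "median", reps=500, seed=2)
        assert out.ci_low > 0.5

    def test_difference_antisymmetric_point_estimate(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(1, 1, 100), rng.normal(0, 1, 100)
        ab = bootstrap_difference_ci(a, b, "median", reps=200, seed=3)
        ba = bootstrap_difference_ci(b, a, "median", reps=200, seed=3)
        assert ab.estimate == pytest.approx(-ba.estimate)
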