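"""Delta statistic, Poisson-surrogate bootstrap and companion tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isoretain.errors import InvalidTableError
from isoretain.resampling import (
    delta_statistic,
    mann_whitney_u,
    permutation_fraction_test,
    poisson_bootstrap_p,
    survival_curve,
    two_sample_t,
)
from isoretain.synthetic import SurvivalSimParams, sim_survival


def make_table(low, high, timepoints=None):
    """Build a survival table from per-timepoint replicate count lists."""
    timepoints = timepoints or list(range(len(low)))
    rows = []
    for pop, data in (("low", low), ("high", high)):
        for t, reps in zip(timepoints, data):
            for i, c in enumerate(np.atleast_1d(reps)):
                rows.append(
                    {"population": pop, "timepoint_h": float(t), "replicate": i,
                     "colonies": int(c)}
                )
    return pd.DataFrame(rows)


class TestDelta:
    def test_worked_example(self):
        table = make_table([10, 8, 6], [9, 5, 4])
        assert delta_statistic(table) == 24 - 18

    def test_identical_populations_give_zero(self):
        table = make_table([5, 4], [5, 4])
        assert delta_statistic(table) == 0

    def test_matches_double_sum(self, rng):
        low = rng.integers(0, 50, size=(3, 2))
        high = rng.integers(0, 50, size=(3, 2))
        table = make_table(list(low), list(high))
        assert delta_statistic(table) == low.sum() - high.sum()

    def test_missing_population_raises(self):
        table = make_table([5], [5])
        with pytest.raises(InvalidTableError):
            delta_statistic(table[table["population"] == "low"])


class TestPoissonBootstrap:
    def test_zero_delta_gives_p_two_of_one(self):
        table = make_table([10, 8], [10, 8])
        res = poisson_bootstrap_p(table, n_surrogates=500, seed=1)
        assert res.p_two_sided == 1.0

    def test_lambda_pools_both_populations(self):
        table = make_table([[10, 14]], [[2, 6]])
        res = poisson_bootstrap_p(table, n_surrogates=10, seed=0)
        assert res.lambdas == {0.0: 8.0}

    def test_bit_for_bit_reproducible(self):
        table = make_table([30, 20, 10], [25, 12, 4])
        r1 = poisson_bootstrap_p(table, n_surrogates=2000, seed=42)
        r2 = poisson_bootstrap_p(table, n_surrogates=2000, seed=42)
        assert (r1.p_one_sided, r1.p_two_sided) == (r2.p_one_sided, r2.p_two_sided)

    def test_label_swap_leaves_two_sided_p_unchanged(self):
        table = make_table([30, 20, 10], [25, 12, 4])
        swapped = table.copy()
        swapped["population"] = swapped["population"].map(
            {"low": "high", "high": "low"}
        )
        r1 = poisson_bootstrap_p(table, n_surrogates=3000, seed=7)
        r2 = poisson_bootstrap_p(swapped, n_surrogates=3000, seed=7)
        assert r1.delta_obs == -r2.delta_obs
        assert r1.p_two_sided == r2.p_two_sided

    def test_add_one_guard_bounds_p_from_below(self):
        table = make_table([200, 180], [20, 10])
        res = poisson_bootstrap_p(table, n_surrogates=1000, seed=3)
        assert res.p_one_sided >= 1 / 1001
        assert res.p_two_sided >= 1 / 1001

    def test_strong_effect_detected(self):
        params = SurvivalSimParams()  # rate_low=0.05 vs rate_high=0.5
        hits = 0
        for seed in range(20):
            table = sim_survival(params, seed=seed)
            res = poisson_bootstrap_p(table, n_surrogates=2000, seed=seed + 1)
            hits += res.p_two_sided < 0.01
        assert hits >= 19


class TestPermutationTest:
    def test_identical_groups_give_large_p(self):
        a = np.array([0, 1] * 10)
        p = permutation_fraction_test(a, a.copy(), n_perm=2000, seed=0)
        assert p > 0.4

    def test_complete_separation_attains_lower_bound(self):
        a = np.zeros(20)
        b = np.ones(20)
        n_perm = 2000
        p = permutation_fraction_test(a, b, n_perm=n_perm, seed=0)
        assert p == pytest.approx(1 / (n_perm + 1))

    def test_matches_exhaustive_enumeration(self, rng):
        a = np.array([0, 0, 1, 0, 1, 0], dtype=float)
        b = np.array([1, 1, 0, 1, 1, 0], dtype=float)
        stat_obs = b.mean() - a.mean()
        pooled = np.concatenate([a, b])
        count = 0
        total = 0
        for comb in itertools.combinations(range(12), 6):
            mask = np.zeros(12, dtype=bool)
            mask[list(comb)] = True
            stat = pooled[~mask].mean() - pooled[mask].mean()
            count += stat >= stat_obs - 1e-12
            total += 1
        exact = count / total
        n_perm = 20_000
        p = permutation_fraction_test(a, b, n_perm=n_perm, seed=5)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) < 3 * se + 1e-4

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            permutation_fraction_test(np.array([]), np.array([1.0]))


class TestMannWhitney:
    def test_exact_separation_example(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], sided="one")
        assert u == 0
        assert p == pytest.approx(1 / math.comb(6, 3))

    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = mann_whitney_u(x, list(x), sided="two")
        assert p == 1.0

    def test_exact_agrees_with_scipy(self, rng):
        for _ in range(25):
            x = rng.normal(size=8)
            y = rng.normal(0.4, 1.0, size=8)
            _, p = mann_whitney_u(x, y, sided="two")
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        for n in (5, 8, 10):
            diffs = []
            for _ in range(20):
                x = rng.normal(size=n)
                y = rng.normal(0.5, 1.0, size=n)
                _, p_exact = mann_whitney_u(x, y, sided="two")
                ref = stats.mannwhitneyu(
                    x, y, alternative="two-sided", method="asymptotic"
                )
                diffs.append(abs(p_exact - ref.pvalue))
            assert max(diffs) < 0.02 + (0.02 if n == 5 else 0.0)


class TestTwoSampleT:
    def test_identical_samples(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_degenerate_variance_flagged(self):
        res = two_sample_t([0.0, 0.0], [1.0, 1.0])
        assert res.degenerate
        assert res.pvalue == 0.0

    def test_matches_scipy_pooled(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(0.3, 1.2, size=15)
        res = two_sample_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_null_calibration(self, rng):
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            rejections += two_sample_t(x, y).pvalue <= 0.05
        assert 0.04 <= rejections / n_rep <= 0.06


class TestSurvivalCurve:
    def test_two_point_arithmetic(self):
        table = make_table([[10, 14]], [[8, 8]])
        curve = survival_curve(table)
        low = curve[curve["population"] == "low"].iloc[0]
        assert low["mean"] == 12.0
        assert low["sem"] == pytest.approx(2.0)

    def test_single_replicate_sem_missing(self):
        table = make_table([[10]], [[8]])
        curve = survival_curve(table)
        assert curve["sem"].isna().all()

    def test_log_slope_matches_decay_rate(self):
        params = SurvivalSimParams(
            rate_low=0.1, rate_high=0.3, cfu0=5000.0,
            timepoints=(0.0, 2.0, 4.0, 6.0, 8.0), replicates=6,
        )
        table = sim_survival(params, seed=9)
        curve = survival_curve(table)
        for pop, rate in (("low", 0.1), ("high", 0.3)):
            sub = curve[curve["population"] == pop]
            slope = np.polyfit(sub["timepoint_h"], np.log(sub["mean"]), 1)[0]
            assert slope == pytest.approx(-rate, abs=0.03)
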