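"""Normality gate, bootstrap mean-difference, and TOST-logic tests."""

import numpy as np
import pytest

from aperio.equivalence import (
    DEFAULT_BOUNDS,
    bootstrap_mean_diff,
    equivalence_test,
    shapiro_wilk,
)
from aperio.reference import PUBLISHED_EQUIVALENCE_TABLE


class TestShapiroWilk:
    def test_normal_samples_mostly_pass(self, rng):
        passes = sum(
            shapiro_wilk(rng.standard_normal(50))[1] > 0.05
            for _ in range(100)
        )
        assert passes >= 90

    def test_lognormal_samples_mostly_fail(self, rng):
        fails = sum(
            shapiro_wilk(np.exp(rng.standard_normal(50) * 1.5))[1] < 0.05
            for _ in range(100)
        )
        assert fails >= 90

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.full(20, 3.0))


class TestBootstrapMeanDiff:
    def test_constant_groups_give_zero(self):
        x = np.full(20, 5.0)
        diff, dist = bootstrap_mean_diff(x, x, n_boot=500, seed=0)
        assert diff == 0.0
        assert np.all(dist == 0.0)

    def test_recovers_true_difference(self, rng):
        xa = rng.standard_normal(500) + 0.1
        xb = rng.standard_normal(500)
        diff, dist = bootstrap_mean_diff(xa, xb, n_boot=3000, seed=1)
        # distribution centers on the observed sample difference, which
        # itself sits near the population value
        assert dist.mean() == pytest.approx(diff, abs=0.005)
        assert diff == pytest.approx(0.1, abs=3 * np.sqrt(2 / 500))

    def test_deterministic_for_fixed_seed(self, rng):
        xa, xb = rng.standard_normal(30), rng.standard_normal(40)
        _, d1 = bootstrap_mean_diff(xa, xb, seed=7, n_boot=200)
        _, d2 = bootstrap_mean_diff(xa, xb, seed=7, n_boot=200)
        assert np.array_equal(d1, d2)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean_diff(np.ones(2), np.ones(10))


class TestEquivalenceTest:
    def test_published_f4_interval_is_not_equivalent(self):
        """The decision rule applied to the printed R^2 F4 row: CI
        [0.006, 0.025] against bound 0.009 fails containment."""
        row = PUBLISHED_EQUIVALENCE_TABLE.set_index("metric").loc["r2_F4"]
        inside = (-row.bound <= row.ci90_low) and (row.ci90_high <= row.bound)
        assert not inside

    def test_identical_large_samples_are_equivalent(self, rng):
        x = rng.standard_normal(500) * 0.01
        res = equivalence_test(x, x.copy(), bound=0.01, n_boot=2000, seed=0)
        assert res.outcome == "equivalent"

    def test_large_true_difference_detected(self, rng):
        """True difference of twice the bound: equivalence is (correctly)
        rejected in at least 95% of replicates."""
        bound = 0.01
        rejected = 0
        reps = 200
        for _ in range(reps):
            xa = rng.standard_normal(500) * 0.02 + 2 * bound
            xb = rng.standard_normal(500) * 0.02
            res = equivalence_test(xa, xb, bound, n_boot=400,
                                   seed=int(rng.integers(2**31)))
            rejected += res.outcome == "not_equivalent"
        assert rejected / reps >= 0.95

    def test_outcome_matches_ci_containment_invariant(self, rng):
        for seed in range(10):
            xa = rng.standard_normal(60) * 0.02 + rng.normal(0, 0.01)
            xb = rng.standard_normal(60) * 0.02
            res = equivalence_test(xa, xb, 0.01, n_boot=500, seed=seed)
            inside = (-res.bound <= res.ci_low) and (res.ci_high <= res.bound)
            assert (res.outcome == "equivalent") == inside

    def test_consistency_as_n_grows(self, rng):
        """With zero true difference, the equivalence rate is monotone
        non-decreasing in n."""
        rates = []
        for n in (25, 100, 400):
            hits = 0
            for _ in range(60):
                xa = rng.standard_normal(n) * 0.02
                xb = rng.standard_normal(n) * 0.02
                res = equivalence_test(xa, xb, 0.01, n_boot=400,
                                       seed=int(rng.integers(2**31)))
                hits += res.equivalent
            rates.append(hits / 60)
        assert rates[0] <= rates[1] <= rates[2]

    def test_percentile_endpoints_are_order_statistics(self, rng):
        """The 90% CI endpoints equal the 5th/95th linear-interpolation
        percentiles of the bootstrap distribution (brute-force sort)."""
        xa, xb = rng.standard_normal(30), rng.standard_normal(30)
        diff, dist = bootstrap_mean_diff(xa, xb, n_boot=200, seed=3)
        res = equivalence_test(xa, xb, 0.5, n_boot=200, seed=3)
        s = np.sort(dist)

        def interp_percentile(q):
            pos = q / 100 * (len(s) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        assert res.ci_low == pytest.approx(interp_percentile(5), abs=1e-12)
        assert res.ci_high == pytest.approx(interp_percentile(95), abs=1e-12)

    def test_invalid_bound_rejected(self, rng):
        with pytest.raises(ValueError):
            equivalence_test(rng.standard_normal(10),
                             rng.standard_normal(10), bound=0.0)

    def test_default_bounds_match_predeclared_margins(self):
        assert DEFAULT_BOUNDS == {"mae": 0.0075, "r2_F3": 0.0102,
                                  "r2_F4": 0.0091}
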