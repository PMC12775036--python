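"""Split-half construction, ICC(2,1), and Delta-ICC bootstrap tests."""

import numpy as np
import pytest

from aperio.recording import Recording
from aperio.reliability import (
    delta_icc_bootstrap,
    icc_2_1,
    icc_2_1_point,
    split_halves,
)
from aperio.validation import icc_anova_oracle


class TestSplitHalves:
    def make_rec(self, n=128 * 240, retained=None):
        data = np.arange(2 * n, dtype=float).reshape(2, n)
        rec = Recording("s", "t", 128.0, ("F3", "F4"), data)
        if retained is not None:
            rec.retained = retained
        return rec

    def test_two_equal_halves_of_240s(self):
        first, second = split_halves(self.make_rec())
        assert first.duration_s == second.duration_s == 120.0

    def test_odd_count_first_half_gets_extra_sample(self):
        rec = self.make_rec(n=128 * 240 + 1)
        first, second = split_halves(rec)
        assert first.n_samples == second.n_samples + 1

    def test_partition_identity(self):
        rec = self.make_rec()
        rec.retained[1000:2000] = False
        first, second = split_halves(rec)
        joined = np.hstack([first.data, second.data])
        assert np.array_equal(joined, rec.data[:, rec.retained])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            split_halves(self.make_rec(n=1000))


class TestICC:
    def test_identical_columns_give_unity(self):
        y = np.column_stack([np.arange(10.0), np.arange(10.0)])
        res = icc_2_1(y)
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_anova_oracle(self, rng):
        """The production ICC agrees with an independent loop-based ANOVA
        decomposition to 1e-10."""
        mats = [
            np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0],
                      [2.0, 1.0]]),
            rng.standard_normal((7, 2)),
            rng.standard_normal((30, 2)) * 2 + 5,
        ]
        for y in mats:
            assert icc_2_1(y).icc == pytest.approx(icc_anova_oracle(y),
                                                   abs=1e-10)

    def test_null_icc_near_zero_for_independent_columns(self, rng):
        y = rng.standard_normal((5000, 2))
        assert abs(icc_2_1(y).icc) < 0.05

    def test_ci_brackets_point_estimate(self, rng):
        t = rng.standard_normal(80)[:, None]
        y = t + rng.standard_normal((80, 2)) * 0.5
        res = icc_2_1(y)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_pingouin_reference(self, rng):
        """Cross-check point estimate and F-based CI against the
        independent pingouin implementation."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        t = rng.standard_normal(40)[:, None]
        y = t + rng.standard_normal((40, 2)) * 0.7
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(40), 2),
            "rater": np.tile([0, 1], 40),
            "score": y.ravel(),
        })
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type").loc["ICC(A,1)"]  # absolute agreement, single
        res = icc_2_1(y)
        assert res.icc == pytest.approx(ref.ICC, abs=1e-8)
        # pingouin prints its CI rounded to 2 decimals
        assert res.ci_low == pytest.approx(ref.CI95[0], abs=0.006)
        assert res.ci_high == pytest.approx(ref.CI95[1], abs=0.006)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(np.ones((4, 2)))

    def test_vectorized_point_matches_scalar(self, rng):
        stack = rng.standard_normal((6, 12, 2))
        vec = icc_2_1_point(stack)
        for i in range(6):
            assert vec[i] == pytest.approx(icc_anova_oracle(stack[i]),
                                           abs=1e-10)


class TestDeltaICC:
    def halves(self, rho, n, rng):
        t = rng.standard_normal(n)[:, None] * np.sqrt(rho)
        return t + rng.standard_normal((n, 2)) * np.sqrt(1 - rho)

    def test_self_comparison_is_null(self, rng):
        y = self.halves(0.7, 60, rng)
        res = delta_icc_bootstrap(y, y, n_boot=2000, seed=0)
        assert res.delta == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_sign_matches_point_estimates(self, rng):
        a = self.halves(0.9, 60, rng)
        b = self.halves(0.4, 60, rng)
        res = delta_icc_bootstrap(a, b, n_boot=2000, seed=1)
        assert np.sign(res.delta) == np.sign(icc_2_1(a).icc - icc_2_1(b).icc)

    def test_known_gap_detected(self, rng):
        a = self.halves(0.95, 80, rng)
        b = self.halves(0.30, 80, rng)
        res = delta_icc_bootstrap(a, b, n_boot=4000, seed=2)
        assert res.ci_low > 0
        assert res.p < 0.05

    def test_bootstrap_ci_coverage_near_nominal(self, rng):
        """Percentile CI for Delta-ICC covers the true zero difference at
        roughly the nominal rate."""
        covered = 0
        reps = 200
        for _ in range(reps):
            a = self.halves(0.6, 100, rng)
            b = self.halves(0.6, 100, rng)
            res = delta_icc_bootstrap(a, b, n_boot=500,
                                      seed=int(rng.integers(2**31)))
            covered += res.ci_low <= 0 <= res.ci_high
        assert covered / reps == pytest.approx(0.95, abs=0.05)

    def test_subsample_stability(self, rng):
        """ICC on a random n=50 subsample of an n=90 cohort stays within
        the subsample CI width of the full-cohort estimate."""
        y = self.halves(0.8, 90, rng)
        full = icc_2_1(y).icc
        sub = icc_2_1(y[rng.choice(90, 50, replace=False)])
        assert abs(sub.icc - full) < (sub.ci_high - sub.ci_low)
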