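"""Bootstrap equivalence testing of fit-quality metrics between systems.

Logic of the two one-sided tests (TOST) procedure, realized
nonparametrically: the distribution of the between-system mean difference
(consumer minus research) is bootstrapped, and equivalence against an
a-priori symmetric bound +/-Delta is concluded exactly when the entire 90%
percentile confidence interval of the difference lies inside
[-Delta, +Delta] (a 90% CI corresponds to two one-sided 5% tests). The
bootstrap route is used because the metric distributions depart from
normality (checked with Shapiro-Wilk); percentile endpoints use the
linear-interpolation order-statistic convention.

Default bounds follow the pre-declared margins for these metrics:
+/-0.0075 for MAE, +/-0.0102 for R^2 at F3, +/-0.0091 for R^2 at F4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_BOUNDS: dict[str, float] = {
    "mae": 0.0075,
    "r2_F3": 0.0102,
    "r2_F4": 0.0091,
}


@dataclass
class EquivalenceResult:
    metric: str
    mean_a: float
    mean_b: float
    mean_diff: float
    ci_low: float
    ci_high: float
    bound: float
    outcome: str  # "equivalent" | "not_equivalent"
    n_boot: int
    seed: int

    @property
    def equivalent(self) -> bool:
        return self.outcome == "equivalent"


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston approximation, via scipy).

    Used to report the normality gate that motivates the bootstrap route.
    """
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: W undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def bootstrap_mean_diff(
    x_a: np.ndarray,
    x_b: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Bootstrap distribution of mean(A*) - mean(B*).

    Each resample draws n_A values from A and n_B from B with replacement
    (unequal group sizes allowed). Returns the observed mean difference
    and the bootstrap distribution.
    """
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    dist = a[idx_a].mean(axis=1) - b[idx_b].mean(axis=1)
    return float(a.mean() - b.mean()), dist


def equivalence_test(
    x_a: np.ndarray,
    x_b: np.ndarray,
    bound: float,
    metric: str = "",
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.90,
) -> EquivalenceResult:
    """Bootstrap percentile-CI equivalence test of A - B against +/-bound.

    A is the consumer-grade group, B the research-grade group; the sign
    convention is consumer minus research.
    """
    if bound <= 0:
        raise ValueError("equivalence bound must be positive")
    mean_diff, dist = bootstrap_mean_diff(x_a, x_b, n_boot=n_boot, seed=seed)
    tail = (1 - ci_level) / 2 * 100
    ci_low, ci_high = np.percentile(dist, [tail, 100 - tail])
    equivalent = (-bound <= ci_low) and (ci_high <= bound)
    return EquivalenceResult(
        metric=metric,
        mean_a=float(np.mean(x_a)),
        mean_b=float(np.mean(x_b)),
        mean_diff=mean_diff,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        bound=bound,
        outcome="equivalent" if equivalent else "not_equivalent",
        n_boot=n_boot,
        seed=seed,
    )


def welch_t_test(x_a: np.ndarray, x_b: np.ndarray) -> tuple[float, float]:
    """Plain two-sample difference test (legacy report; the headline
    analysis is the equivalence test)."""
    t, p = stats.ttest_ind(x_a, x_b, equal_var=False)
    return float(t), float(p)
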