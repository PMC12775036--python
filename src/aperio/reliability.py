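"""Split-half reliability of aperiodic parameters.

Within-system reliability is quantified by the single-measure, absolute-
agreement intraclass correlation from a two-way random-effects model,
ICC(2,1), computed on an n-subjects x 2-halves matrix of one parameter:

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

with k = 2 raters (recording halves), MS_R / MS_C / MS_E the row (subject),
column (half), and residual mean squares of the two-way ANOVA
decomposition. The 95% CI uses the standard F-distribution construction
for this ICC form (McGraw & Wong, 1996, Psychological Methods 1:30-46).

Between-system reliability differences are assessed by a nonparametric
bootstrap of Delta-ICC = ICC_A - ICC_B: subjects are resampled with
replacement independently within each system at each system's own n, the
ICC difference recomputed per resample, and a 95% percentile CI with a
two-sided percentile p-value reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .recording import Recording


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    model: str = "ICC(2,1) absolute agreement"
    degenerate: bool = False


@dataclass
class DeltaICCResult:
    delta: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    seed: int
    n_redrawn: int = 0


def split_halves(rec: Recording, min_samples_per_half: int = 2048
                 ) -> tuple[Recording, Recording]:
    """Contiguous first/second halves of the retained data.

    The split is on retained samples; for odd counts the first half gets
    the extra sample. Concatenating the halves reproduces the retained
    signal exactly.
    """
    idx = np.flatnonzero(rec.retained)
    m = idx.size
    h = (m + 1) // 2
    if h < min_samples_per_half or m - h < min_samples_per_half:
        raise ValueError(
            f"retained duration too short to split: {m} samples, "
            f"need {2 * min_samples_per_half}"
        )
    halves = []
    for part in (idx[:h], idx[h:]):
        halves.append(Recording(
            subject=rec.subject, system=rec.system, fs=rec.fs,
            channels=tuple(rec.channels), data=rec.data[:, part],
        ))
    return halves[0], halves[1]


def _mean_squares(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-way ANOVA mean squares for stacked (..., n, k) matrices."""
    n, k = y.shape[-2], y.shape[-1]
    grand = y.mean(axis=(-2, -1), keepdims=True)
    rows = y.mean(axis=-1, keepdims=True)
    cols = y.mean(axis=-2, keepdims=True)
    ss_rows = (k * (rows - grand) ** 2).sum(axis=(-2, -1))
    ss_cols = (n * (cols - grand) ** 2).sum(axis=(-2, -1))
    ss_total = ((y - grand) ** 2).sum(axis=(-2, -1))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return ms_r, ms_c, ms_e


def _icc_from_ms(ms_r, ms_c, ms_e, n: int, k: int):
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom != 0, (ms_r - ms_e) / denom, np.nan)


def icc_2_1(pm: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with F-based 95% CI for an n x 2 paired-measurement matrix."""
    y = np.asarray(pm, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("paired measurements must be an n x 2 matrix")
    n, k = y.shape
    if n < 5:
        raise ValueError("at least 5 subjects required for the CI")
    ms_r, ms_c, ms_e = _mean_squares(y)
    if ms_r == 0 and ms_e == 0:
        return ICCResult(np.nan, np.nan, np.nan, n, degenerate=True)
    icc = float(_icc_from_ms(ms_r, ms_c, ms_e, n, k))
    if not np.isfinite(icc):
        return ICCResult(np.nan, np.nan, np.nan, n, degenerate=True)

    # McGraw & Wong F-based interval for single-measure absolute agreement
    fj = ms_c / ms_e if ms_e > 0 else np.inf
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and ms_e > 0:
        v = (a * ms_c + b * ms_e) ** 2 / (
            (a * ms_c) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (ms_r - f1 * ms_e) / (
            f1 * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r
        )
        upper = n * (f2 * ms_r - ms_e) / (
            k * ms_c + (k * n - k - n) * ms_e + n * f2 * ms_r
        )
    else:  # perfect agreement: interval collapses
        lower = upper = icc
    lower, upper = float(min(lower, icc)), float(max(upper, icc))
    return ICCResult(icc=icc, ci_low=lower, ci_high=upper, n=n)


def icc_2_1_point(stacked: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) point estimates for (..., n, 2) stacks."""
    y = np.asarray(stacked, dtype=float)
    ms_r, ms_c, ms_e = _mean_squares(y)
    return _icc_from_ms(ms_r, ms_c, ms_e, y.shape[-2], y.shape[-1])


def delta_icc_bootstrap(
    pm_a: np.ndarray,
    pm_b: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    max_redraws: int = 100,
) -> DeltaICCResult:
    """Bootstrap the between-system difference in ICC(2,1).

    Subjects are resampled with replacement independently within each
    group (at each group's own n). Resamples with a degenerate ICC are
    redrawn and counted.
    """
    a = np.asarray(pm_a, dtype=float)
    b = np.asarray(pm_b, dtype=float)
    rng = np.random.default_rng(seed)

    def boot(y: np.ndarray, size: int) -> np.ndarray:
        idx = rng.integers(0, y.shape[0], size=(size, y.shape[0]))
        return icc_2_1_point(y[idx])

    icc_a = boot(a, n_boot)
    icc_b = boot(b, n_boot)
    delta = icc_a - icc_b
    n_redrawn = 0
    for _ in range(max_redraws):
        bad = ~np.isfinite(delta)
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        delta[bad] = boot(a, int(bad.sum())) - boot(b, int(bad.sum()))
    ci_low, ci_high = np.percentile(delta, [2.5, 97.5])
    p = 2 * min((delta <= 0).mean(), (delta >= 0).mean())
    point = float(icc_2_1(a).icc - icc_2_1(b).icc)
    return DeltaICCResult(
        delta=point, ci_low=float(ci_low), ci_high=float(ci_high),
        p=float(min(p, 1.0)), n_boot=n_boot, seed=seed, n_redrawn=n_redrawn,
    )
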