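"""General signal-quality metrics and within-session stability.

Quality is summarized per subject and channel by mean log10 power in the
49-51 Hz band (mains line noise) and the 0.1-1 Hz band (low-frequency
electrode drift), both computed on the preprocessed, filtered data, plus
the fraction of segments retained after artifact rejection. Within-session
stability compares first- versus second-half band powers with a paired
Wilcoxon signed-rank test.

Band power is averaged in log10 space; values are log10(uV^2/Hz), so more
negative numbers mean less power in the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import PowerSpectrum

LINE_BAND_HZ = (49.0, 51.0)
DRIFT_BAND_HZ = (0.1, 1.0)


def band_power(ps: PowerSpectrum, lo: float, hi: float) -> float:
    """Mean log10 power over grid points with lo <= f <= hi (inclusive)."""
    m = (ps.freqs >= lo) & (ps.freqs <= hi)
    if not m.any():
        raise ValueError(
            f"band [{lo}, {hi}] Hz does not intersect the frequency grid "
            f"[{ps.freqs[0]}, {ps.freqs[-1]}]"
        )
    return float(np.mean(np.log10(ps.power[m])))


@dataclass
class StabilityResult:
    statistic: float
    p: float
    median_change: float
    n: int
    degenerate: bool = False


def halfwise_stability(first: np.ndarray, second: np.ndarray) -> StabilityResult:
    """Paired Wilcoxon signed-rank test of second-half minus first-half
    values. Zero differences are dropped (classical convention); if all
    differences are zero the result is flagged degenerate rather than
    raising."""
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if first.shape != second.shape:
        raise ValueError("halves must be paired")
    if first.size < 6:
        raise ValueError("at least 6 pairs required")
    diff = second - first
    if np.all(diff == 0):
        return StabilityResult(np.nan, np.nan, 0.0, first.size, degenerate=True)
    stat, p = stats.wilcoxon(second, first, zero_method="wilcox",
                             alternative="two-sided")
    return StabilityResult(
        statistic=float(stat), p=float(p),
        median_change=float(np.median(diff)), n=first.size,
    )


def quality_table(
    spectra: dict[str, dict[str, PowerSpectrum]],
    retention: pd.DataFrame,
    system: str,
) -> pd.DataFrame:
    """Per subject x channel line-noise and drift band powers.

    ``spectra`` maps subject -> channel -> full-recording PowerSpectrum.
    """
    ret = retention.set_index("subject")["retention"]
    rows = []
    for subject, by_ch in spectra.items():
        for channel, ps in by_ch.items():
            rows.append(dict(
                subject=subject, system=system, channel=channel,
                line_noise=band_power(ps, *LINE_BAND_HZ),
                drift=band_power(ps, *DRIFT_BAND_HZ),
                retention=float(ret.get(subject, np.nan)),
            ))
    return pd.DataFrame(rows)


def quality_summary(
    report_a: pd.DataFrame,
    report_b: pd.DataFrame,
    exclusions: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-system mean/range of each quality metric in one comparison table.

    ``exclusions`` maps system name -> (n_excluded, n_total).
    """
    rows = []
    for rep in (report_a, report_b):
        system = rep.system.iloc[0]
        row = dict(system=system)
        for metric in ("line_noise", "drift", "retention"):
            row[f"{metric}_mean"] = float(rep[metric].mean())
            row[f"{metric}_min"] = float(rep[metric].min())
            row[f"{metric}_max"] = float(rep[metric].max())
        if exclusions and system in exclusions:
            row["n_excluded"], row["n_total"] = exclusions[system]
        rows.append(row)
    return pd.DataFrame(rows)


def signed_rank_brute(diff: np.ndarray) -> float:
    """Exact W+ rank sum for small samples (independent oracle for tests)."""
    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    ranks = stats.rankdata(np.abs(diff))
    return float(ranks[diff > 0].sum())
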