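"""Brain-behavior statistics.

Links the frontal aperiodic composite (mean of offset and exponent at F3
and F4) to arithmetic fluency and working memory: Pearson correlation with
a Fisher-transform CI, comparison of correlations across independent
samples by Fisher's Z, and a supplementary simple mediation (indirect
effect a*b with a case-resampling percentile bootstrap CI). All continuous
variables are z-standardized before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class CorrelationResult:
    r: float
    p: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class MediationResult:
    a: float          # x -> m
    b: float          # m -> y given x
    c: float          # total x -> y
    c_prime: float    # direct x -> y given m
    indirect: float   # a * b
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n: int


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 (ddof=1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input cannot be standardized")
    return (x - x.mean()) / sd


def pearson_ci(x: np.ndarray, y: np.ndarray,
               ci_level: float = 0.95) -> CorrelationResult:
    """Pearson r with a two-sided t-test p and Fisher-transform CI.

    CI: atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3), back-transformed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    t = r * np.sqrt((n - 2) / max(1 - r**2, np.finfo(float).tiny))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    zcrit = stats.norm.ppf(0.5 + ci_level / 2)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = zcrit / np.sqrt(n - 3)
    return CorrelationResult(
        r=r, p=p, ci_low=float(np.tanh(z - half)),
        ci_high=float(np.tanh(z + half)), n=n,
    )


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int
                     ) -> tuple[float, float]:
    """Fisher's Z test comparing two correlations from independent samples.

    Z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both samples need n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1 / (n1 - 3) + 1 / (n2 - 3)
    )
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p


def _ols_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray
               ) -> tuple[float, float, float, float]:
    a = sm.OLS(m, sm.add_constant(x)).fit().params[1]
    fit_mx = sm.OLS(y, sm.add_constant(np.column_stack([x, m]))).fit()
    c_prime, b = fit_mx.params[1], fit_mx.params[2]
    c = sm.OLS(y, sm.add_constant(x)).fit().params[1]
    return float(a), float(b), float(c), float(c_prime)


def simple_mediation(
    x: np.ndarray, m: np.ndarray, y: np.ndarray,
    n_boot: int = 5000, seed: int = 0, standardize: bool = True,
) -> MediationResult:
    """Simple mediation x -> m -> y with a percentile bootstrap CI for the
    indirect effect a*b (case resampling). On standardized OLS fits the
    identity c = c' + a*b holds exactly."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    x, m, y = x[ok], m[ok], y[ok]
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    if standardize:
        x, m, y = zscore(x), zscore(m), zscore(y)
    a, b, c, c_prime = _ols_paths(x, m, y)
    rng = np.random.default_rng(seed)
    # closed-form OLS inside the bootstrap (identical estimates, no
    # per-resample model-object overhead)
    idx = rng.integers(0, n, size=(n_boot, n))
    xs, ms, ys = x[idx], m[idx], y[idx]
    xc = xs - xs.mean(axis=1, keepdims=True)
    mc = ms - ms.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    sxx = (xc * xc).sum(axis=1)
    smm = (mc * mc).sum(axis=1)
    sxm = (xc * mc).sum(axis=1)
    sxy = (xc * yc).sum(axis=1)
    smy = (mc * yc).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_star = sxm / sxx
        det = sxx * smm - sxm**2
        b_star = (sxx * smy - sxm * sxy) / det
    indirects = a_star * b_star
    indirects = indirects[np.isfinite(indirects)]
    ci_low, ci_high = np.percentile(indirects, [2.5, 97.5])
    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, indirect=a * b,
        ci_low=float(ci_low), ci_high=float(ci_high),
        n_boot=n_boot, seed=seed, n=n,
    )


def correlation_report(
    composites: pd.Series, behavior: pd.DataFrame
) -> pd.DataFrame:
    """Correlations of the aperiodic composite and working memory with
    math ability, z-standardizing all measures first."""
    merged = behavior.set_index("subject").join(
        composites.rename("composite"), how="inner"
    ).dropna(subset=["composite", "math"])
    rows = []
    pairs = [
        ("composite", "math"),
        ("composite", "wm_verbal"),
        ("composite", "wm_visuospatial"),
        ("wm_verbal", "math"),
        ("wm_visuospatial", "math"),
    ]
    for xa, ya in pairs:
        res = pearson_ci(zscore(merged[xa].to_numpy()),
                         zscore(merged[ya].to_numpy()))
        rows.append(dict(x=xa, y=ya, r=res.r, p=res.p,
                         ci_low=res.ci_low, ci_high=res.ci_high, n=res.n))
    return pd.DataFrame(rows)
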