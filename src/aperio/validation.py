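"""Self-contained validation studies for the whole pipeline.

Each function runs one verifiable study — an arithmetic worked example
from the published summary table, an oracle-equivalence sweep, a
parameter-recovery or calibration simulation — and returns a dict of
named scalar results, ``{name: {"value": float, "n": int}}``. They are
exercised both by the test suite and by the reproduction script.

Problem sizes are fixed here (cohort sizes, replicate counts, bootstrap
sizes) as a balance between Monte-Carlo error and single-CPU runtime;
docs/methods.md lists them.
"""

from __future__ import annotations

import inspect

import numpy as np
import pandas as pd

from . import crossval, equivalence, quality, reference, reliability
from .association import fisher_z_compare, pearson_ci
from .preprocess import preprocess_recording
from .profiles import device_profile
from .reliability import icc_2_1, icc_2_1_point
from .spectral import PowerSpectrum, fit_spectrum, welch_psd
from .synth import (
    Peak,
    SpectralParams,
    oracle_psd,
    synth_behavior,
    synth_recording,
)

ANALYTIC_GRID = np.arange(1.0, 40.0 + 1e-9, 0.125)


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# published-table arithmetic

def table1_arithmetic() -> dict:
    """Consumer-minus-research differences of the printed per-system means
    for the R^2 F4 and MAE F4 rows of the published equivalence table."""
    return {
        "table1_mean_diff_r2_f4": {
            "value": reference.mean_difference_from_printed_means("r2_F4"),
            "n": 2,
        },
        "table1_mean_diff_mae_f4": {
            "value": reference.mean_difference_from_printed_means("mae_F4"),
            "n": 2,
        },
    }


# ---------------------------------------------------------------------------
# spectral fit oracle equivalence

def fit_oracle_cases() -> list[SpectralParams]:
    cases = []
    for b in (-2.0, 0.0, 2.0):
        for chi in (0.0, 1.5, 3.0):
            cases.append(SpectralParams(b, chi))
            cases.append(SpectralParams(b, chi, (Peak(10.0, 0.6, 2.0),)))
            cases.append(SpectralParams(
                b, chi, (Peak(8.0, 0.5, 2.0), Peak(25.0, 0.4, 3.0))
            ))
    return cases


def fit_oracle_equivalence() -> dict:
    """Fit noiseless analytic spectra; worst-case parameter error, worst
    R^2 and MAE across the sweep."""
    max_err = 0.0
    worst_r2, worst_mae = 1.0, 0.0
    cases = fit_oracle_cases()
    for params in cases:
        ps = PowerSpectrum("F3", ANALYTIC_GRID,
                           oracle_psd(ANALYTIC_GRID, params))
        fit = fit_spectrum(ps)
        errs = [abs(fit.offset - params.offset),
                abs(fit.exponent - params.exponent)]
        if len(fit.peaks) == len(params.peaks):
            for est, true in zip(
                sorted(fit.peaks), sorted((p.cf, p.pw, p.bw) for p in params.peaks)
            ):
                errs.append(abs(est[0] - true[0]))
        else:
            errs.append(np.inf)
        max_err = max(max_err, max(errs))
        worst_r2 = min(worst_r2, fit.r2)
        worst_mae = max(worst_mae, fit.mae)
    return {
        "fit_oracle_max_abs_param_error": {"value": float(max_err),
                                           "n": len(cases)},
        "fit_oracle_min_r2": {"value": float(worst_r2), "n": len(cases)},
        "fit_oracle_max_mae": {"value": float(worst_mae), "n": len(cases)},
    }


# ---------------------------------------------------------------------------
# parameter recovery from synthesized recordings

def parameter_recovery(seed: int = 0, n_subjects: int = 50,
                       duration_s: float = 240.0) -> dict:
    """Median absolute recovery error of exponent and offset across
    subjects, per device profile, for full-length recordings."""
    rng = np.random.default_rng(seed)
    out = {}
    for short, profile_name in (("consumer", "emotiv_like"),
                                ("research", "biosemi_like")):
        profile = device_profile(profile_name)
        errs_chi, errs_b = [], []
        seeds = _spawn(seed + hash(profile_name) % 1000, n_subjects)
        for i in range(n_subjects):
            b = rng.normal(0.5, 0.4)
            chi = max(rng.normal(1.3, 0.25), 0.3)
            pk = Peak(rng.normal(9, 1), max(rng.normal(0.5, 0.15), 0.1), 2.0)
            p = SpectralParams(b, chi, (pk,))
            rec, _ = synth_recording(
                {c: (p, p) for c in profile.channels}, profile, duration_s,
                seed=seeds[i],
            )
            clean, _ = preprocess_recording(rec)
            fit = fit_spectrum(welch_psd(clean, "F3"))
            errs_chi.append(fit.exponent - chi)
            errs_b.append(fit.offset - b)
        out[f"exponent_recovery_median_abs_bias_{short}"] = {
            "value": float(np.median(np.abs(errs_chi))), "n": n_subjects}
        out[f"offset_recovery_median_abs_bias_{short}"] = {
            "value": float(np.median(np.abs(errs_b))), "n": n_subjects}
    return out


# ---------------------------------------------------------------------------
# ICC oracle and plug-in consistency

def icc_anova_oracle(y: np.ndarray) -> float:
    """Brute-force ICC(2,1) from an explicit two-way ANOVA decomposition,
    written independently of the production path (loops, no shared code)."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = y.mean()
    ss_rows = sum(k * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


def icc_oracle_and_consistency(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    mats = [np.array([[1., 2.], [3., 4.], [5., 6.], [7., 8.], [2., 1.]]),
            rng.normal(size=(8, 2)), rng.normal(size=(12, 2)) * 3 + 1]
    for y in mats:
        max_diff = max(max_diff, abs(icc_2_1(y).icc - icc_anova_oracle(y)))
    out = {"icc_oracle_max_abs_diff": {"value": float(max_diff),
                                       "n": len(mats)}}
    # plug-in consistency: halves = t + e with var(t)/(var(t)+var(e)) = R;
    # bias estimated as the mean estimation error over replicates
    n, n_reps = 2000, 50
    for r_true in (0.5, 0.9):
        t = rng.standard_normal((n_reps, n, 1)) * np.sqrt(r_true)
        e = rng.standard_normal((n_reps, n, 2)) * np.sqrt(1 - r_true)
        iccs = icc_2_1_point(t + e)
        key = f"icc_plugin_abs_bias_r{int(r_true * 100):02d}"
        out[key] = {"value": float(abs(iccs.mean() - r_true)), "n": n}
    return out


# ---------------------------------------------------------------------------
# equivalence-test size and power

def _equivalence_rate(
    true_diff: float, bound: float, n_per_group: int, n_reps: int,
    seed: int, n_boot: int = 1000,
) -> float:
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        xa = rng.standard_normal(n_per_group) * 0.02 + true_diff
        xb = rng.standard_normal(n_per_group) * 0.02
        idx_a = rng.integers(0, n_per_group, size=(n_boot, n_per_group))
        idx_b = rng.integers(0, n_per_group, size=(n_boot, n_per_group))
        dist = xa[idx_a].mean(axis=1) - xb[idx_b].mean(axis=1)
        lo, hi = np.percentile(dist, [5, 95])
        hits += (-bound <= lo) and (hi <= bound)
    return hits / n_reps


def equivalence_size_and_power(seed: int = 0) -> dict:
    """TOST operating characteristics: the rate of (wrongly) concluding
    equivalence when the true difference sits exactly on the bound, and
    the rate of (correctly) concluding it under a zero true difference
    with large samples."""
    bound = 0.01
    s1, s2 = _spawn(seed, 2)
    size = _equivalence_rate(true_diff=bound, bound=bound, n_per_group=100,
                             n_reps=1000, seed=s1)
    power = _equivalence_rate(true_diff=0.0, bound=bound, n_per_group=400,
                              n_reps=400, seed=s2)
    return {
        "tost_size_at_bound": {"value": float(size), "n": 1000},
        "tost_power_null_diff_n400": {"value": float(power), "n": 400},
    }


# ---------------------------------------------------------------------------
# split-half reliability pattern

def _cohort_exponent_halves(rho_half: float, n: int, seed: int,
                            duration_s: float, profile_name: str) -> np.ndarray:
    """Fitted exponent n x 2 matrix (halves) from full signal synthesis."""
    from .reliability import split_halves
    from .synth import synth_cohort

    profile = device_profile(profile_name)
    recs, truth = synth_cohort(
        n, profile, duration_s=duration_s, seed=seed,
        param_distributions={"rho_half": rho_half},
    )
    rows = []
    for rec in recs:
        clean, _ = preprocess_recording(rec)
        first, second = split_halves(clean)
        rows.append([fit_spectrum(welch_psd(h, "F3")).exponent
                     for h in (first, second)])
    return np.asarray(rows)


def reliability_pattern(seed: int = 0, n_subjects: int = 80) -> dict:
    """Full-pipeline split-half ICC of the exponent under high and low
    generator stability, plus the rate at which the Delta-ICC bootstrap
    separates cohorts with a known reliability gap."""
    s_hi, s_lo, s_sep = _spawn(seed, 3)
    icc_hi = icc_2_1(_cohort_exponent_halves(0.95, n_subjects, s_hi,
                                             240.0, "emotiv_like")).icc
    icc_lo = icc_2_1(_cohort_exponent_halves(0.30, n_subjects, s_lo,
                                             240.0, "emotiv_like")).icc

    # separation power at the parameter level (known reliability gap)
    rng = np.random.default_rng(s_sep)
    n_reps, n_grp, excluded = 50, 80, 0
    for _ in range(n_reps):
        def halves(rho):
            t = rng.standard_normal(n_grp)[:, None] * np.sqrt(rho)
            return t + rng.standard_normal((n_grp, 2)) * np.sqrt(1 - rho)
        d = reliability.delta_icc_bootstrap(
            halves(0.95), halves(0.30), n_boot=2000,
            seed=int(rng.integers(2**31)),
        )
        excluded += (d.ci_low > 0) or (d.ci_high < 0)
    return {
        "icc_exponent_rho095": {"value": float(icc_hi), "n": n_subjects},
        "icc_exponent_rho030": {"value": float(icc_lo), "n": n_subjects},
        "delta_icc_separation_rate": {"value": excluded / n_reps, "n": n_reps},
    }


# ---------------------------------------------------------------------------
# behavior calibration and Fisher-Z type I error

def association_recovery(seed: int = 0) -> dict:
    s1, s2 = _spawn(seed, 2)
    rng = np.random.default_rng(s1)
    n_reps, n = 500, 90
    rs = []
    for i in range(n_reps):
        x = rng.standard_normal(n) * 0.3 + 0.9  # composite-like scale
        beh = synth_behavior(x, target_r=-0.23, seed=int(rng.integers(2**31)))
        rs.append(np.corrcoef(x, beh.math_raw)[0, 1])
    mean_r = float(np.mean(rs))

    rng = np.random.default_rng(s2)
    n_reps_z, rejections = 1000, 0
    rho = -0.23
    cov = np.array([[1, rho], [rho, 1]])
    chol = np.linalg.cholesky(cov)
    for _ in range(n_reps_z):
        a = (chol @ rng.standard_normal((2, 90)))
        b = (chol @ rng.standard_normal((2, 50)))
        r1 = np.corrcoef(a)[0, 1]
        r2 = np.corrcoef(b)[0, 1]
        _, p = fisher_z_compare(r1, 90, r2, 50)
        rejections += p < 0.05
    return {
        "behavior_mean_r_preclip": {"value": mean_r, "n": n_reps},
        "fisher_z_type1_rate": {"value": rejections / n_reps_z, "n": n_reps_z},
    }


# ---------------------------------------------------------------------------
# quality contrast between device profiles

def quality_contrast(seed: int = 0, n_reps: int = 50, n_subjects: int = 6,
                     duration_s: float = 60.0) -> dict:
    """Fraction of paired synthetic cohorts in which the consumer profile
    shows higher line-noise and drift band power than the research
    profile (band powers on filtered data, as in the analysis)."""
    seeds = _spawn(seed, n_reps)
    line_wins = drift_wins = 0
    p = SpectralParams(0.5, 1.3, (Peak(9.0, 0.5, 2.0),))
    for rep_seed in seeds:
        ss = np.random.SeedSequence(rep_seed).spawn(2 * n_subjects)
        means = {}
        for k, profile_name in enumerate(("emotiv_like", "biosemi_like")):
            profile = device_profile(profile_name)
            line, drift = [], []
            for i in range(n_subjects):
                rec, _ = synth_recording(
                    {c: (p, p) for c in profile.channels}, profile,
                    duration_s, seed=ss[k * n_subjects + i],
                    inject_artifacts=False,
                )
                clean, _ = preprocess_recording(rec)
                ps = welch_psd(clean, "F3")
                line.append(quality.band_power(ps, *quality.LINE_BAND_HZ))
                drift.append(quality.band_power(ps, *quality.DRIFT_BAND_HZ))
            means[profile_name] = (np.mean(line), np.mean(drift))
        line_wins += means["emotiv_like"][0] > means["biosemi_like"][0]
        drift_wins += means["emotiv_like"][1] > means["biosemi_like"][1]
    return {
        "quality_line_noise_contrast_rate": {"value": line_wins / n_reps,
                                             "n": n_reps},
        "quality_drift_contrast_rate": {"value": drift_wins / n_reps,
                                        "n": n_reps},
    }


# ---------------------------------------------------------------------------
# cross-validation floor and error-sensitivity calibration

def synthetic_long_table(n_subjects: int, seed: int) -> pd.DataFrame:
    """Long-format table whose values depend only on the categorical cell
    plus noise — the regime where the cell-mean predictor is optimal."""
    rng = np.random.default_rng(seed)
    cell_means = {"F3_offset": 0.5, "F3_exponent": 1.3,
                  "F4_offset": 0.55, "F4_exponent": 1.25}
    rows = []
    for s in range(n_subjects):
        for label, mu in cell_means.items():
            rows.append(dict(subject=f"s{s:03d}", system="emotiv_like",
                             label=label,
                             value=mu + rng.standard_normal() * 0.25))
    return pd.DataFrame(rows)


def crossval_floor(seed: int = 0, n_subjects: int = 90) -> dict:
    s1, s2 = _spawn(seed, 2)
    long = synthetic_long_table(n_subjects, s1)
    gp = crossval.crossval_regression(long, "gaussian_process", seed=s2)
    base = crossval.crossval_regression(long, "group_mean_baseline", seed=s2)
    ratio = gp.mse / base.mse

    # homogeneous residual sets (all errors of equal magnitude): the
    # trimming effect is exactly zero, so its CI must cover 0
    rng = np.random.default_rng(s2)
    n_reps, covered = 200, 0
    for _ in range(n_reps):
        c = rng.uniform(0.5, 2.0)
        resid = c * rng.choice([-1.0, 1.0], size=200)
        res = crossval.error_sensitivity(
            resid, n_boot=500, seed=int(rng.integers(2**31)))
        covered += res.ci_low <= 0 <= res.ci_high
    return {
        "gp_vs_cellmean_mse_ratio": {"value": float(ratio), "n": 4 * n_subjects},
        "error_sensitivity_null_coverage": {"value": covered / n_reps,
                                            "n": n_reps},
    }


ALL_STUDIES = (
    table1_arithmetic,
    fit_oracle_equivalence,
    parameter_recovery,
    icc_oracle_and_consistency,
    equivalence_size_and_power,
    reliability_pattern,
    association_recovery,
    quality_contrast,
    crossval_floor,
)


def run_all(seed: int = 0) -> dict:
    """Run every validation study with streams derived from one seed."""
    results: dict = {}
    seeds = _spawn(seed, len(ALL_STUDIES))
    for fn, s in zip(ALL_STUDIES, seeds):
        kwargs = {"seed": s} if "seed" in inspect.signature(fn).parameters else {}
        results.update(fn(**kwargs))
    return results
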