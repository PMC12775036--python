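"""End-to-end orchestration: synthesize two cohorts, preprocess, fit
spectra, and run the reliability / equivalence / quality / cross-validation
/ association analyses with one seeded configuration.

Every stochastic stage derives its stream from the single master seed, so
a fixed configuration reproduces byte-identical reports. The run manifest
records settings, seeds, and subject counts at every filter so the
counting always balances (subjects in = excluded + analyzed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, crossval, equivalence, quality, reliability
from .preprocess import apply_exclusion_rule, preprocess_recording
from .profiles import device_profile
from .recording import Recording
from .spectral import aperiodic_composite, fit_quality, fit_spectrum, welch_psd
from .synth import subject_truth_composite, synth_behavior, synth_cohort


@dataclass
class PipelineConfig:
    consumer_profile: str = "emotiv_like"
    research_profile: str = "biosemi_like"
    n_consumer: int = 93   # before exclusion, as in the study design
    n_research: int = 52
    duration_s: float = 240.0
    seg_len_s: float = 1.0
    amp_threshold_uv: float = 100.0
    target_fs: float = 128.0
    bounds: dict = field(default_factory=lambda: dict(equivalence.DEFAULT_BOUNDS))
    n_boot_equivalence: int = 10_000
    n_boot_delta_icc: int = 10_000
    n_boot_sensitivity: int = 10_000
    n_boot_mediation: int = 5000
    behavior_target_r: float = -0.23
    behavior_wm_r: float = 0.3
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        for metric in ("mae", "r2_F3", "r2_F4"):
            if metric not in self.bounds:
                raise ValueError(f"bounds map is missing an entry for {metric!r}")
        device_profile(self.consumer_profile)
        device_profile(self.research_profile)


def _fit_tables(recordings: list[Recording], channels=("F3", "F4")):
    """Full-recording and half-wise spectral fits plus quality band powers."""
    fit_rows, spectra = [], {}
    for rec in recordings:
        spectra[rec.subject] = {}
        first, second = reliability.split_halves(rec)
        for ch in channels:
            for half_label, source in (("full", rec), ("1", first), ("2", second)):
                ps = welch_psd(source, ch)
                fit = fit_spectrum(ps)
                r2, mae = fit_quality(fit, ps)
                fit_rows.append(dict(
                    subject=rec.subject, system=rec.system, channel=ch,
                    half=half_label, offset=fit.offset, exponent=fit.exponent,
                    n_peaks=fit.n_peaks, r2=r2, mae=mae,
                ))
                if half_label == "full":
                    spectra[rec.subject][ch] = ps
                else:
                    spectra[rec.subject][f"{ch}_h{half_label}"] = ps
    return pd.DataFrame(fit_rows), spectra


def process_cohort(profile_name, n, cfg: PipelineConfig, seed_seq):
    profile = device_profile(profile_name)
    cohort_ss, behavior_ss = seed_seq.spawn(2)
    recordings, truth = synth_cohort(
        n, profile, duration_s=cfg.duration_s, seed=cohort_ss,
    )
    cleaned, ret_rows = [], []
    for rec in recordings:
        clean, frac = preprocess_recording(
            rec, cfg.seg_len_s, cfg.amp_threshold_uv, cfg.target_fs,
        )
        cleaned.append(clean)
        ret_rows.append(dict(subject=rec.subject, system=profile_name,
                             retention=frac))
    report = apply_exclusion_rule(pd.DataFrame(ret_rows))
    kept = set(report.retained_subjects)
    analyzed = [r for r in cleaned if r.subject in kept]
    fits, spectra = _fit_tables(analyzed)
    behavior = synth_behavior(
        subject_truth_composite(truth).loc[sorted(kept)],
        target_r=cfg.behavior_target_r, wm_r=cfg.behavior_wm_r,
        seed=behavior_ss,
    )
    return dict(
        profile=profile_name, truth=truth, retention=report, fits=fits,
        spectra=spectra, behavior=behavior, n_in=n, n_analyzed=len(analyzed),
    )


def _paired_param_matrix(fits: pd.DataFrame, channel: str, param: str):
    halves = fits[fits.half.isin(["1", "2"])]
    wide = halves.pivot_table(index="subject", columns="half", values=param)
    wide = wide.dropna() if channel is None else (
        halves[halves.channel == channel]
        .pivot(index="subject", columns="half", values=param).dropna()
    )
    return wide[["1", "2"]].to_numpy()


def _composites(fits: pd.DataFrame) -> pd.Series:
    full = fits[fits.half == "full"]
    out = {}
    for subject, grp in full.groupby("subject"):
        fits_by_ch = {r.channel: r for _, r in grp.iterrows()}
        vals = []
        for ch in ("F3", "F4"):
            vals += [fits_by_ch[ch].offset, fits_by_ch[ch].exponent]
        out[subject] = float(np.mean(vals))
    return pd.Series(out, name="composite")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the report bundle (optionally also
    written as delimited tables plus a JSON manifest)."""
    cfg.validate()
    master = np.random.SeedSequence(cfg.seed)
    ss_consumer, ss_research, ss_stats = master.spawn(3)
    stat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss_stats.spawn(8)]

    consumer = process_cohort(cfg.consumer_profile, cfg.n_consumer, cfg, ss_consumer)
    research = process_cohort(cfg.research_profile, cfg.n_research, cfg, ss_research)

    # --- equivalence of fit-quality metrics (full-recording fits) -------
    eq_rows = []
    full_a = consumer["fits"][consumer["fits"].half == "full"]
    full_b = research["fits"][research["fits"].half == "full"]
    for metric, col, ch in (("r2_F3", "r2", "F3"), ("r2_F4", "r2", "F4"),
                            ("mae_F3", "mae", "F3"), ("mae_F4", "mae", "F4")):
        xa = full_a[full_a.channel == ch][col].to_numpy()
        xb = full_b[full_b.channel == ch][col].to_numpy()
        bound = cfg.bounds.get(metric, cfg.bounds["mae"])
        res = equivalence.equivalence_test(
            xa, xb, bound, metric=metric, n_boot=cfg.n_boot_equivalence,
            seed=stat_seeds[0],
        )
        w, p_norm = equivalence.shapiro_wilk(np.concatenate([xa, xb]))
        eq_rows.append({**asdict(res), "shapiro_w": w, "shapiro_p": p_norm})
    equivalence_table = pd.DataFrame(eq_rows)

    # --- split-half reliability ----------------------------------------
    icc_rows, delta_rows = [], []
    for ch in ("F3", "F4"):
        for param in ("offset", "exponent"):
            pm = {}
            for name, coh in (("consumer", consumer), ("research", research)):
                pm[name] = _paired_param_matrix(coh["fits"], ch, param)
                r = reliability.icc_2_1(pm[name])
                icc_rows.append(dict(
                    system=coh["profile"], channel=ch, parameter=param,
                    icc=r.icc, ci_low=r.ci_low, ci_high=r.ci_high, n=r.n,
                ))
            d = reliability.delta_icc_bootstrap(
                pm["consumer"], pm["research"],
                n_boot=cfg.n_boot_delta_icc, seed=stat_seeds[1],
            )
            delta_rows.append(dict(
                channel=ch, parameter=param, delta_icc=d.delta,
                ci_low=d.ci_low, ci_high=d.ci_high, p=d.p,
            ))
    reliability_table = pd.DataFrame(icc_rows)
    delta_icc_table = pd.DataFrame(delta_rows)

    # --- general quality and stability ---------------------------------
    qual = {}
    for name, coh in (("consumer", consumer), ("research", research)):
        full_spectra = {
            s: {ch: ps for ch, ps in by.items() if "_h" not in ch}
            for s, by in coh["spectra"].items()
        }
        qual[name] = quality.quality_table(
            full_spectra, coh["retention"].table, coh["profile"],
        )
    stability_rows = []
    for name, coh in (("consumer", consumer), ("research", research)):
        for band_name, band in (("line_noise", quality.LINE_BAND_HZ),
                                ("drift", quality.DRIFT_BAND_HZ)):
            firsts, seconds = [], []
            for s, by in coh["spectra"].items():
                for ch in ("F3", "F4"):
                    firsts.append(quality.band_power(by[f"{ch}_h1"], *band))
                    seconds.append(quality.band_power(by[f"{ch}_h2"], *band))
            st = quality.halfwise_stability(np.array(firsts), np.array(seconds))
            stability_rows.append(dict(
                system=coh["profile"], band=band_name, W=st.statistic,
                p=st.p, median_change=st.median_change, n=st.n,
            ))
    quality_summary = quality.quality_summary(
        qual["consumer"], qual["research"],
        exclusions={
            consumer["profile"]: (consumer["retention"].n_excluded, consumer["n_in"]),
            research["profile"]: (research["retention"].n_excluded, research["n_in"]),
        },
    )
    stability_table = pd.DataFrame(stability_rows)

    # --- cross-validation ----------------------------------------------
    cv_rows, sens_rows = [], []
    for name, coh in (("consumer", consumer), ("research", research)):
        long = crossval.build_long_table(coh["fits"][coh["fits"].half == "full"])
        long, n_out = crossval.remove_outliers(long)
        for model in ("gaussian_process", "random_forest", "group_mean_baseline"):
            res = crossval.crossval_regression(long, model=model,
                                               seed=stat_seeds[2])
            cv_rows.append(dict(
                system=coh["profile"], model=model, mse=res.mse, mae=res.mae,
                median_ae=res.median_ae, n_train=res.n_train,
                n_test=res.n_test, n_outliers_removed=n_out,
            ))
            if model == "gaussian_process" and res.residuals.size - 3 >= 10:
                sens = crossval.error_sensitivity(
                    res.residuals, n_boot=cfg.n_boot_sensitivity,
                    seed=stat_seeds[3],
                )
                sens_rows.append(dict(
                    system=coh["profile"], delta_mae=sens.delta_mae,
                    ci_low=sens.ci_low, ci_high=sens.ci_high, p=sens.p,
                ))
    cv_table = pd.DataFrame(cv_rows)
    sensitivity_table = pd.DataFrame(sens_rows)

    # --- association ----------------------------------------------------
    comp_a = _composites(consumer["fits"])
    comp_b = _composites(research["fits"])
    corr_a = association.correlation_report(comp_a, consumer["behavior"])
    corr_b = association.correlation_report(comp_b, research["behavior"])
    ra = corr_a[(corr_a.x == "composite") & (corr_a.y == "math")].iloc[0]
    rb = corr_b[(corr_b.x == "composite") & (corr_b.y == "math")].iloc[0]
    z, p_z = association.fisher_z_compare(ra.r, int(ra.n), rb.r, int(rb.n))
    beh = consumer["behavior"].set_index("subject").join(comp_a, how="inner")
    wm_mean = beh[["wm_verbal", "wm_visuospatial"]].mean(axis=1)
    if len(beh) >= 10:
        med = association.simple_mediation(
            beh.composite.to_numpy(), wm_mean.to_numpy(),
            beh.math.to_numpy().astype(float),
            n_boot=cfg.n_boot_mediation, seed=stat_seeds[4],
        )
        mediation_table = pd.DataFrame([asdict(med)])
    else:  # supplementary analysis needs at least 10 complete cases
        mediation_table = pd.DataFrame()
    association_tables = dict(
        consumer=corr_a, research=corr_b,
        fisher_z=pd.DataFrame([dict(z=z, p=p_z)]),
        mediation=mediation_table,
    )

    manifest = dict(
        config={k: v for k, v in asdict(cfg).items()},
        stat_seeds=stat_seeds,
        counts={
            name: dict(
                subjects_in=coh["n_in"],
                excluded=coh["retention"].n_excluded,
                analyzed=coh["n_analyzed"],
            )
            for name, coh in (("consumer", consumer), ("research", research))
        },
    )
    for name, c in manifest["counts"].items():
        assert c["subjects_in"] == c["excluded"] + c["analyzed"], name

    bundle = dict(
        fits_consumer=consumer["fits"], fits_research=research["fits"],
        retention_consumer=consumer["retention"].table,
        retention_research=research["retention"].table,
        behavior_consumer=consumer["behavior"],
        behavior_research=research["behavior"],
        equivalence=equivalence_table,
        reliability=reliability_table, delta_icc=delta_icc_table,
        quality_consumer=qual["consumer"], quality_research=qual["research"],
        quality_summary=quality_summary, stability=stability_table,
        crossval=cv_table, sensitivity=sensitivity_table,
        association=association_tables, manifest=manifest,
    )
    if cfg.out_dir:
        write_bundle(bundle, cfg.out_dir)
    return bundle


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def dump(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.6g")

    for key, value in bundle.items():
        if key == "manifest":
            (out / "manifest.json").write_text(
                json.dumps(value, indent=2, default=str) + "\n"
            )
        elif key == "association":
            for sub, df in value.items():
                dump(df, f"association_{sub}")
        elif isinstance(value, pd.DataFrame):
            dump(value, key)
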