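"""Synthetic resting-state EEG cohorts with known aperiodic ground truth.

The generator emulates two independent child cohorts recorded on different
acquisition systems (see :mod:`aperio.profiles`). Each subject's spectrum
follows the standard aperiodic + periodic decomposition,

    log10 P(f) = b - chi * log10 f + sum_i PW_i * exp(-(f - CF_i)^2 / (2 s_i^2)),

with s_i = BW_i / 2, offset ``b`` in log10(uV^2/Hz) at 1 Hz, exponent
``chi`` the magnitude of the log-log slope, and one alpha-band peak per
subject by default. Time series are synthesized by random-phase spectral
shaping (amplitude sqrt of the target PSD, uniform phases, inverse FFT),
which makes the analytic model spectrum an exact oracle for the expected
Welch estimate. Device-specific nuisance terms (50 Hz mains, a ~32 Hz
harmonic bump, low-frequency drift, high-amplitude artifact bursts) are
added on top per the device profile.

Split-half parameter stability is a generator knob: the recording is built
as two contiguous halves whose standardized parameters are correlated
``rho_half`` across halves (v_h = sqrt(rho)*T + sqrt(1-rho)*e_h with T
subject-stable), so the downstream split-half ICC of a perfectly estimated
parameter equals ``rho_half``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import DeviceProfile
from .recording import Recording

# Population defaults for child frontal resting-state spectra. The exponent
# and offset distributions are plausible for 9-10-year-olds; no published
# distributional parameters exist for this population, so these are fixed
# generator conventions, not estimates.
DEFAULT_PARAM_DISTRIBUTIONS: dict = {
    "exponent_mean": 1.3,
    "exponent_sd": 0.25,
    "exponent_min": 0.3,     # truncation floor
    "offset_mean": 0.5,
    "offset_sd": 0.4,
    "offset_exponent_corr": 0.6,
    "alpha_cf_mean": 9.0,
    "alpha_cf_sd": 1.0,
    "alpha_pw_mean": 0.5,
    "alpha_pw_sd": 0.15,
    "alpha_pw_min": 0.1,
    "alpha_bw_mean": 2.0,
    "alpha_bw_sd": 0.4,
    "alpha_bw_limits": (1.0, 6.0),
    "rho_half": 0.9,         # cross-half parameter correlation
    "channel_share": 0.9,    # fraction of variance shared between F3/F4
}

BUMP_CF_HZ = 32.0    # center of the consumer-device harmonic bump
BUMP_SD_HZ = 1.5
DRIFT_SD_HZ = 0.35   # half-Gaussian low-pass scale of the drift spectrum
BURST_AMP_UV = 500.0
BURST_LEN_S = 1.0


@dataclass(frozen=True)
class Peak:
    cf: float   # center frequency, Hz
    pw: float   # height, log10 power units
    bw: float   # bandwidth (2 sigma), Hz


@dataclass(frozen=True)
class SpectralParams:
    offset: float
    exponent: float
    peaks: tuple[Peak, ...] = ()


def oracle_psd(freqs: np.ndarray, params: SpectralParams) -> np.ndarray:
    """Noiseless model PSD (uV^2/Hz) on a positive frequency grid."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("oracle_psd requires strictly positive frequencies")
    log_p = params.offset - params.exponent * np.log10(freqs)
    for pk in params.peaks:
        sigma = pk.bw / 2.0
        log_p = log_p + pk.pw * np.exp(-((freqs - pk.cf) ** 2) / (2 * sigma**2))
    return 10.0 ** log_p


def _shaped_noise(n: int, fs: float, psd_fn, rng: np.random.Generator) -> np.ndarray:
    """Random-phase realization whose expected one-sided PSD is psd_fn(f)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros(freqs.size)
    pos = freqs > 0
    # |X_k|^2 = S(f_k) * fs * n / 2 gives a one-sided density of S(f)
    amp[pos] = np.sqrt(psd_fn(freqs[pos]) * fs * n / 2.0)
    phases = rng.uniform(0.0, 2 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1]  # Nyquist bin must be real
    return np.fft.irfft(spec, n=n)


def _band_limited_noise(
    n: int, fs: float, center: float, sd: float, rms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if rms <= 0:
        return np.zeros(n)
    x = _shaped_noise(
        n, fs, lambda f: np.exp(-((f - center) ** 2) / (2 * sd**2)), rng
    )
    s = x.std()
    return x * (rms / s) if s > 0 else x


def synth_channel_half(
    params: SpectralParams, profile: DeviceProfile, n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One contiguous half of one channel: shaped 1/f + device nuisance."""
    x = _shaped_noise(n, profile.fs, lambda f: oracle_psd(f, params), rng)
    if profile.line_noise_amp > 0:
        t = np.arange(n) / profile.fs
        x += profile.line_noise_amp * np.sin(
            2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
        )
    if profile.harmonic_bump_amp > 0:
        x += _band_limited_noise(
            n, profile.fs, BUMP_CF_HZ, BUMP_SD_HZ, profile.harmonic_bump_amp, rng
        )
    if profile.drift_amp > 0:
        x += _band_limited_noise(
            n, profile.fs, 0.0, DRIFT_SD_HZ, profile.drift_amp, rng
        )
    return x


def synth_recording(
    half_params: dict[str, tuple[SpectralParams, SpectralParams]],
    profile: DeviceProfile,
    duration_s: float,
    seed: int | np.random.SeedSequence,
    subject: str = "s000",
    inject_artifacts: bool = True,
) -> tuple[Recording, np.ndarray]:
    """Synthesize one recording from per-channel, per-half ground truth.

    Returns the recording and the ground-truth boolean mask of samples
    covered by injected artifact bursts (for testing segment rejection).
    """
    if duration_s < 8:
        raise ValueError("duration_s must be at least 8 s (one Welch window)")
    rng = np.random.default_rng(seed)
    n_half = int(round(duration_s * profile.fs / 2))
    n = 2 * n_half
    channels = tuple(profile.channels)
    data = np.empty((len(channels), n))
    for i, ch in enumerate(channels):
        p1, p2 = half_params[ch]
        data[i, :n_half] = synth_channel_half(p1, profile, n_half, rng)
        data[i, n_half:] = synth_channel_half(p2, profile, n_half, rng)

    burst_mask = np.zeros(n, dtype=bool)
    if inject_artifacts and profile.artifact_rate > 0:
        seg_len = int(round(BURST_LEN_S * profile.fs))
        n_segs = n // seg_len
        n_bursts = min(int(rng.poisson(profile.artifact_rate * n_segs)), n_segs)
        if n_bursts:
            hit = rng.choice(n_segs, size=n_bursts, replace=False)
            # zero-mean square wave: the full burst amplitude inside the
            # window, negligible low-frequency content outside it
            t = np.arange(seg_len) / profile.fs
            wave = BURST_AMP_UV * np.sign(np.sin(2 * np.pi * 2.0 * t) + 1e-12)
            for s in hit:
                sl = slice(s * seg_len, (s + 1) * seg_len)
                signs = rng.choice([-1.0, 1.0], size=len(channels))
                data[:, sl] += wave * signs[:, None]
                burst_mask[sl] = True

    rec = Recording(
        subject=subject, system=profile.name, fs=profile.fs,
        channels=channels, data=data,
    )
    return rec, burst_mask


def draw_half_parameters(
    n: int,
    rng: np.random.Generator,
    dist: dict | None = None,
) -> pd.DataFrame:
    """Draw per-subject x channel x half aperiodic parameters and peaks.

    Returns a tidy frame with one row per (subject, channel, half) where
    half is 1 or 2, plus the standardized latent columns used internally.
    Offset and exponent are correlated ``offset_exponent_corr`` at the
    stable-subject level; cross-half correlation of each parameter is
    exactly ``rho_half``; F3/F4 share ``channel_share`` of the variance.
    """
    if n < 2:
        raise ValueError("cohort size must be at least 2")
    d = dict(DEFAULT_PARAM_DISTRIBUTIONS)
    if dist:
        unknown = set(dist) - set(d)
        if unknown:
            raise ValueError(f"unknown distribution parameters: {sorted(unknown)}")
        d.update(dist)
    rho = d["rho_half"]
    if not 0 <= rho <= 1:
        raise ValueError("rho_half must be in [0, 1]")
    if d["exponent_sd"] < 0 or d["offset_sd"] < 0:
        raise ValueError("distribution SDs must be non-negative")
    lam = 1.0 - d["channel_share"]
    channels = ("F3", "F4")

    # Latent standardized scores: subject-stable T (channel-shared plus
    # channel-specific parts) and independent half-specific innovations e.
    rows = []
    rho_bc = d["offset_exponent_corr"]
    chol = np.linalg.cholesky(np.array([[1.0, rho_bc], [rho_bc, 1.0]]))
    for s in range(n):
        sid = f"s{s:03d}"
        # subject-stable latents for (offset, exponent), channel-shared
        T_shared = chol @ rng.standard_normal(2)
        T_chan = {c: chol @ rng.standard_normal(2) for c in channels}
        # one alpha peak per subject, stable across halves and channels
        cf = rng.normal(d["alpha_cf_mean"], d["alpha_cf_sd"])
        pw = max(rng.normal(d["alpha_pw_mean"], d["alpha_pw_sd"]), d["alpha_pw_min"])
        bw = float(np.clip(
            rng.normal(d["alpha_bw_mean"], d["alpha_bw_sd"]), *d["alpha_bw_limits"]
        ))
        for c in channels:
            T = np.sqrt(1 - lam) * T_shared + np.sqrt(lam) * T_chan[c]
            for h in (1, 2):
                e = chol @ rng.standard_normal(2)
                v = np.sqrt(rho) * T + np.sqrt(1 - rho) * e
                offset = d["offset_mean"] + d["offset_sd"] * v[0]
                exponent = max(
                    d["exponent_mean"] + d["exponent_sd"] * v[1],
                    d["exponent_min"],
                )
                rows.append(
                    dict(subject=sid, channel=c, half=h, offset=offset,
                         exponent=exponent, peak_cf=cf, peak_pw=pw, peak_bw=bw)
                )
    return pd.DataFrame(rows)


def truth_params(truth: pd.DataFrame, subject: str, channel: str,
                 half: int) -> SpectralParams:
    row = truth[(truth.subject == subject) & (truth.channel == channel)
                & (truth.half == half)]
    if row.empty:
        raise KeyError(f"no ground truth for {subject}/{channel}/half{half}")
    r = row.iloc[0]
    return SpectralParams(
        offset=float(r.offset), exponent=float(r.exponent),
        peaks=(Peak(float(r.peak_cf), float(r.peak_pw), float(r.peak_bw)),),
    )


def subject_truth_composite(truth: pd.DataFrame) -> pd.Series:
    """Ground-truth aperiodic composite per subject.

    Mean of offset and exponent over channels F3/F4 (halves averaged first),
    matching the composite the analysis computes from fitted spectra.
    """
    per_sc = truth.groupby(["subject", "channel"])[["offset", "exponent"]].mean()
    return per_sc.stack().groupby("subject").mean()


def synth_cohort(
    n: int,
    profile: DeviceProfile,
    duration_s: float = 240.0,
    seed: int | np.random.SeedSequence = 0,
    param_distributions: dict | None = None,
    inject_artifacts: bool = True,
) -> tuple[list[Recording], pd.DataFrame]:
    """Generate a cohort of recordings plus its ground-truth table.

    One master seed spawns independent per-subject streams, so subject k's
    recording is unchanged when the cohort grows.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    param_ss, *rest = ss.spawn(1 + n)
    truth = draw_half_parameters(
        n, np.random.default_rng(param_ss), param_distributions
    )
    recordings = []
    mask_rows = []
    for s, sub_ss in enumerate(rest):
        sid = f"s{s:03d}"
        half_params = {
            ch: (truth_params(truth, sid, ch, 1), truth_params(truth, sid, ch, 2))
            for ch in profile.channels
        }
        rec, burst = synth_recording(
            half_params, profile, duration_s, sub_ss, subject=sid,
            inject_artifacts=inject_artifacts,
        )
        recordings.append(rec)
        mask_rows.append(burst)
    truth.attrs["burst_masks"] = dict(
        zip([r.subject for r in recordings], mask_rows)
    )
    return recordings, truth


# -- behavior ---------------------------------------------------------------

MATH_MEAN = 101.97   # published cohort mean of the timed arithmetic score
MATH_SD = 27.57
MATH_RANGE = (0, 200)
WM_MEANS = {"wm_verbal": 0.65, "wm_visuospatial": 0.60}
WM_SD = 0.15


def synth_behavior(
    composites: pd.Series | np.ndarray,
    target_r: float = -0.23,
    wm_r: float = 0.3,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Behavioral scores correlated with the aperiodic composite.

    The math score is built as math_z = target_r * x_z + sqrt(1-r^2) * eps,
    rescaled to the published mean/SD, rounded, and clipped to [0, 200];
    ``math_raw`` preserves the pre-rounding, pre-clipping value so
    calibration can measure the unattenuated correlation. Working-memory
    proportions are built against the math score with correlation ``wm_r``
    and clipped to [0, 1].
    """
    if not -1 < target_r < 1:
        raise ValueError("target_r must be in (-1, 1)")
    x = np.asarray(composites, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    subjects = (
        list(composites.index) if isinstance(composites, pd.Series)
        else [f"s{i:03d}" for i in range(x.size)]
    )
    rng = np.random.default_rng(seed)
    xz = (x - x.mean()) / x.std(ddof=1)
    math_z = target_r * xz + np.sqrt(1 - target_r**2) * rng.standard_normal(x.size)
    math_raw = MATH_MEAN + MATH_SD * math_z
    math = np.clip(np.round(math_raw), *MATH_RANGE).astype(int)
    out = {"subject": subjects, "math": math, "math_raw": math_raw}
    mz = (math_raw - math_raw.mean()) / math_raw.std(ddof=1)
    for col, mean in WM_MEANS.items():
        wz = wm_r * mz + np.sqrt(1 - wm_r**2) * rng.standard_normal(x.size)
        out[col] = np.clip(mean + WM_SD * wz, 0.0, 1.0)
    return pd.DataFrame(out)
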