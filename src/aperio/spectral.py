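"""Welch PSD estimation and parameterization of the power spectrum into
aperiodic (offset, exponent) and periodic (Gaussian peak) components.

The decomposition models the log-power spectrum over 1-40 Hz as

    log10 P(f) = b - chi * log10 f + sum_i PW_i * exp(-(f-CF_i)^2 / (2 s_i^2))

with s_i = BW_i / 2 and per-peak bandwidth BW clamped to configured limits
(defaults [1, 8] Hz, at most 5 peaks, no knee). Fitting proceeds as:

1. robust initial straight-line fit of log10 P on log10 f (fit, discard the
   top 2.5% positive residuals, refit) to seed the aperiodic component;
2. iterative peak extraction: locate the largest residual maximum, fit a
   single Gaussian around it (width clamped to the limits), subtract, and
   repeat until the residual apex drops below the detection threshold
   (2.0 residual SDs by default, with a small absolute floor so numerical
   noise on exact model input is never fit as a peak) or the peak cap is
   reached;
3. refit the aperiodic line on the peak-stripped spectrum;
4. assemble the final model and diagnostics.

One additional strip/refit refinement round is run by default: re-deriving
the peaks from the refined aperiodic fit and refitting the line once more
removes the residual slope bias a large alpha peak exerts on the seed fit.

Fit quality follows the convention of the spectral parameterization
literature: R^2 is the squared Pearson correlation between modeled and
observed log10 power, MAE the mean absolute error in log10 power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.optimize import curve_fit

from .recording import Recording

WELCH_NPERSEG = 1024
WELCH_OVERLAP = 0.75
FIT_RANGE_HZ = (1.0, 40.0)
PEAK_WIDTH_LIMITS_HZ = (1.0, 8.0)  # bandwidth = 2 sigma
MAX_N_PEAKS = 5
PEAK_THRESHOLD_SD = 2.0
PEAK_MIN_HEIGHT = 0.0
_RESIDUAL_FLOOR = 1e-6  # absolute stop floor for peak detection


@dataclass
class PowerSpectrum:
    channel: str
    freqs: np.ndarray   # Hz, strictly increasing
    power: np.ndarray   # uV^2/Hz, one-sided density
    subject: str = ""
    system: str = ""
    half: str = "full"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("frequency and power grids differ in length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def band(self, lo: float, hi: float) -> "PowerSpectrum":
        m = (self.freqs >= lo) & (self.freqs <= hi)
        return PowerSpectrum(self.channel, self.freqs[m], self.power[m],
                             self.subject, self.system, self.half)


@dataclass
class SpectralFit:
    offset: float
    exponent: float
    peaks: list[tuple[float, float, float]]  # (CF Hz, PW log10, BW Hz)
    r2: float
    mae: float
    fit_range: tuple[float, float]
    converged: bool = True
    notes: str = ""
    settings: dict = field(default_factory=dict)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def model(self, freqs: np.ndarray) -> np.ndarray:
        """Modeled log10 power on a positive frequency grid."""
        freqs = np.asarray(freqs, dtype=float)
        y = self.offset - self.exponent * np.log10(freqs)
        for cf, pw, bw in self.peaks:
            s = bw / 2.0
            y = y + pw * np.exp(-((freqs - cf) ** 2) / (2 * s**2))
        return y


def welch_psd(
    rec: Recording,
    channel: str,
    nperseg: int = WELCH_NPERSEG,
    overlap: float = WELCH_OVERLAP,
) -> PowerSpectrum:
    """Welch PSD of the retained samples of one channel (Hann taper,
    one-sided density scaling). At 128 Hz and nperseg=1024 the grid step
    is 0.125 Hz."""
    x = rec.channel_data(channel, retained_only=True)
    if x.size < nperseg:
        raise ValueError(
            f"only {x.size} retained samples; at least {nperseg} required"
        )
    freqs, power = sp_signal.welch(
        x, fs=rec.fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend="constant", scaling="density",
    )
    return PowerSpectrum(
        channel=channel, freqs=freqs, power=power,
        subject=rec.subject, system=rec.system,
    )


def _linfit(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(logf, logp, 1)
    return float(intercept), float(-slope)  # offset, exponent


def _robust_aperiodic(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    b, chi = _linfit(logf, logp)
    resid = logp - (b - chi * logf)
    pos = resid > 0
    if pos.any():
        cut = np.quantile(resid[pos], 0.975)
        keep = ~(resid >= cut)
        if keep.sum() >= 3:
            b, chi = _linfit(logf[keep], logp[keep])
    return b, chi


def _gauss(f, height, center, sigma):
    return height * np.exp(-((f - center) ** 2) / (2 * sigma**2))


def _fit_one_peak(
    freqs: np.ndarray, resid: np.ndarray, width_limits: tuple[float, float]
) -> tuple[float, float, float] | None:
    i = int(np.argmax(resid))
    apex, cf0 = resid[i], freqs[i]
    s_lo, s_hi = width_limits[0] / 2.0, width_limits[1] / 2.0
    # half-height width guess from the residual profile
    half = apex / 2.0
    j = i
    while j + 1 < resid.size and resid[j] > half:
        j += 1
    k = i
    while k - 1 >= 0 and resid[k] > half:
        k -= 1
    fwhm = max(freqs[j] - freqs[k], 2 * 1.177 * s_lo)
    s0 = float(np.clip(fwhm / 2.355, s_lo, s_hi))
    try:
        popt, _ = curve_fit(
            _gauss, freqs, resid,
            p0=[apex, cf0, s0],
            bounds=([0.0, freqs[0], s_lo], [np.inf, freqs[-1], s_hi]),
            maxfev=5000,
        )
    except RuntimeError:
        return None
    height, center, sigma = popt
    return float(center), float(height), float(2 * sigma)


def _extract_peaks(
    freqs: np.ndarray,
    flat: np.ndarray,
    max_n_peaks: int,
    threshold_sd: float,
    min_height: float,
    width_limits: tuple[float, float],
) -> list[tuple[float, float, float]]:
    peaks: list[tuple[float, float, float]] = []
    resid = flat.copy()
    for _ in range(max_n_peaks):
        stop = max(threshold_sd * resid.std(), min_height, _RESIDUAL_FLOOR)
        if resid.max() < stop:
            break
        pk = _fit_one_peak(freqs, resid, width_limits)
        if pk is None:
            break
        cf, pw, bw = pk
        if pw < max(min_height, _RESIDUAL_FLOOR):
            break
        peaks.append(pk)
        resid = resid - _gauss(freqs, pw, cf, bw / 2.0)
    return peaks


def fit_spectrum(
    ps: PowerSpectrum,
    fit_range: tuple[float, float] = FIT_RANGE_HZ,
    max_n_peaks: int = MAX_N_PEAKS,
    peak_width_limits: tuple[float, float] = PEAK_WIDTH_LIMITS_HZ,
    peak_threshold_sd: float = PEAK_THRESHOLD_SD,
    peak_min_height: float = PEAK_MIN_HEIGHT,
    n_refinements: int = 1,
) -> SpectralFit:
    """Parameterize one spectrum into aperiodic + Gaussian-peak components."""
    lo, hi = fit_range
    m = (ps.freqs >= lo) & (ps.freqs <= hi)
    if m.sum() < 8:
        raise ValueError(f"grid must cover [{lo}, {hi}] Hz with enough points")
    freqs = ps.freqs[m]
    power = ps.power[m]
    if not np.all(np.isfinite(power)) or np.any(power <= 0):
        raise ValueError("power values in the fit range must be finite and positive")
    logf = np.log10(freqs)
    logp = np.log10(power)

    b, chi = _robust_aperiodic(logf, logp)
    peaks: list[tuple[float, float, float]] = []
    converged = True
    notes = ""
    for _ in range(1 + n_refinements):
        flat = logp - (b - chi * logf)
        peaks = _extract_peaks(
            freqs, flat, max_n_peaks, peak_threshold_sd, peak_min_height,
            peak_width_limits,
        )
        stripped = logp.copy()
        for cf, pw, bw in peaks:
            stripped -= _gauss(freqs, pw, cf, bw / 2.0)
        b, chi = _linfit(logf, stripped)

    model = b - chi * logf
    for cf, pw, bw in peaks:
        model += _gauss(freqs, pw, cf, bw / 2.0)
    r2, mae = _quality(model, logp)
    if not np.isfinite(r2):
        converged = False
        notes = "degenerate spectrum: R^2 undefined"
        r2 = np.nan
    return SpectralFit(
        offset=b, exponent=chi, peaks=peaks, r2=r2, mae=mae,
        fit_range=(lo, hi), converged=converged, notes=notes,
        settings=dict(
            max_n_peaks=max_n_peaks, peak_width_limits=peak_width_limits,
            peak_threshold_sd=peak_threshold_sd,
            peak_min_height=peak_min_height, n_refinements=n_refinements,
        ),
    )


def _quality(model: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    mae = float(np.mean(np.abs(model - observed)))
    if np.std(observed) == 0 or np.std(model) == 0:
        # perfect constant-offset case: correlation undefined
        return (1.0 if mae == 0 else np.nan), mae
    r = float(np.corrcoef(model, observed)[0, 1])
    return r * r, mae


def fit_quality(fit: SpectralFit, ps: PowerSpectrum) -> tuple[float, float]:
    """R^2 (squared correlation) and MAE of a fit, in log10-power space
    over the fit range."""
    lo, hi = fit.fit_range
    m = (ps.freqs >= lo) & (ps.freqs <= hi)
    freqs = ps.freqs[m]
    logp = np.log10(ps.power[m])
    model = fit.model(freqs)
    return _quality(model, logp)


def aperiodic_composite(fits: dict[str, SpectralFit]) -> float:
    """Mean of offset and exponent over frontal channels F3 and F4."""
    values = []
    for ch in ("F3", "F4"):
        if ch not in fits:
            raise KeyError(f"channel {ch} required for the aperiodic composite")
        values += [fits[ch].offset, fits[ch].exponent]
    return float(np.mean(values))
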