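"""Welch estimation and spectral-parameterization tests."""

import numpy as np
import pytest

from aperio.recording import Recording
from aperio.spectral import (
    PowerSpectrum,
    aperiodic_composite,
    fit_quality,
    fit_spectrum,
    welch_psd,
)
from aperio.synth import Peak, SpectralParams, oracle_psd
from aperio.preprocess import downsample, preprocess_recording
from conftest import make_recording


def analytic_spectrum(params, grid):
    return PowerSpectrum("F3", grid, oracle_psd(grid, params))


class TestWelch:
    def test_frequency_resolution(self):
        rec = Recording("s", "t", 128.0, ("F3", "F4"),
                        np.random.default_rng(0).standard_normal((2, 128 * 60)))
        ps = welch_psd(rec, "F3")
        assert np.diff(ps.freqs)[0] == pytest.approx(128 / 1024)

    def test_parseval_variance_check(self, rng):
        x = rng.standard_normal((2, 128 * 240))
        rec = Recording("s", "t", 128.0, ("F3", "F4"), x)
        ps = welch_psd(rec, "F3")
        total = np.trapezoid(ps.power, ps.freqs)
        assert total == pytest.approx(1.0, rel=0.05)

    def test_tone_located_at_its_bin(self):
        t = np.arange(128 * 60) / 128
        x = np.sin(2 * np.pi * 10.0 * t)
        rec = Recording("s", "t", 128.0, ("F3", "F4"), np.vstack([x, x]))
        ps = welch_psd(rec, "F3")
        assert ps.freqs[np.argmax(ps.power)] == pytest.approx(10.0, abs=1e-9)

    def test_missing_channel_raises(self, consumer_recording):
        with pytest.raises(KeyError, match="Cz"):
            welch_psd(consumer_recording[0], "Cz")


class TestFitSpectrum:
    def test_model_in_model_out(self, analytic_grid):
        ps = analytic_spectrum(SpectralParams(1.0, 1.5), analytic_grid)
        fit = fit_spectrum(ps)
        assert fit.offset == pytest.approx(1.0, abs=1e-3)
        assert fit.exponent == pytest.approx(1.5, abs=1e-3)
        assert fit.n_peaks == 0
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)
        assert fit.mae == pytest.approx(0.0, abs=1e-6)

    def test_single_gaussian_recovered(self, analytic_grid):
        ps = analytic_spectrum(
            SpectralParams(1.0, 1.5, (Peak(10.0, 0.6, 2.0),)), analytic_grid)
        fit = fit_spectrum(ps)
        assert fit.n_peaks == 1
        cf, pw, bw = fit.peaks[0]
        assert cf == pytest.approx(10.0, abs=0.25)

    def test_peak_cap_respected(self, analytic_grid):
        peaks = tuple(Peak(cf, 0.5, 2.0) for cf in (5, 10, 15, 20, 25, 30, 35))
        ps = analytic_spectrum(SpectralParams(1.0, 1.0, peaks), analytic_grid)
        fit = fit_spectrum(ps)
        assert fit.n_peaks <= 5

    def test_bandwidths_within_limits(self, analytic_grid):
        ps = analytic_spectrum(
            SpectralParams(0.5, 1.3, (Peak(9.0, 0.5, 2.0),)), analytic_grid)
        for _, _, bw in fit_spectrum(ps).peaks:
            assert 1.0 <= bw <= 8.0

    def test_oracle_equivalence_sweep(self, analytic_grid):
        """Across offsets, exponents, and 0-2 well-separated peaks the
        recovered aperiodic parameters stay within 1e-2 of truth."""
        for b in (-2.0, 0.0, 2.0):
            for chi in (0.0, 1.5, 3.0):
                for peaks in ((), (Peak(10.0, 0.6, 2.0),),
                              (Peak(8.0, 0.5, 2.0), Peak(25.0, 0.4, 3.0))):
                    ps = analytic_spectrum(SpectralParams(b, chi, peaks),
                                           analytic_grid)
                    fit = fit_spectrum(ps)
                    assert fit.offset == pytest.approx(b, abs=1e-2)
                    assert fit.exponent == pytest.approx(chi, abs=1e-2)
                    assert fit.n_peaks == len(peaks)

    def test_nonfinite_power_rejected(self, analytic_grid):
        power = oracle_psd(analytic_grid, SpectralParams(1.0, 1.0))
        power[5] = np.nan
        with pytest.raises(ValueError):
            fit_spectrum(PowerSpectrum("F3", analytic_grid, power))

    def test_hardware_bump_does_not_bias_exponent(self, analytic_grid):
        """A narrow 30-35 Hz bump is absorbed as a peak, moving the fitted
        exponent by less than 0.1."""
        base = SpectralParams(1.0, 1.5, (Peak(10.0, 0.6, 2.0),))
        bumped = SpectralParams(1.0, 1.5, (Peak(10.0, 0.6, 2.0),
                                           Peak(32.0, 0.3, 2.5)))
        f0 = fit_spectrum(analytic_spectrum(base, analytic_grid))
        f1 = fit_spectrum(analytic_spectrum(bumped, analytic_grid))
        assert abs(f1.exponent - f0.exponent) < 0.1

    def test_noise_degrades_fit_monotonically(self, analytic_grid, rng):
        """Median R^2 non-increasing and MAE non-decreasing as log-power
        noise SD grows."""
        base = np.log10(oracle_psd(analytic_grid,
                                   SpectralParams(1.0, 1.5,
                                                  (Peak(10.0, 0.6, 2.0),))))
        r2s, maes = [], []
        for sd in (0.01, 0.05, 0.15):
            r2_rep, mae_rep = [], []
            for _ in range(50):
                noisy = 10 ** (base + rng.standard_normal(base.size) * sd)
                fit = fit_spectrum(PowerSpectrum("F3", analytic_grid, noisy))
                r2_rep.append(fit.r2)
                mae_rep.append(fit.mae)
            r2s.append(np.median(r2_rep))
            maes.append(np.median(mae_rep))
        assert r2s[0] >= r2s[1] >= r2s[2]
        assert maes[0] <= maes[1] <= maes[2]

    def test_downsampling_equivalence(self, alpha_params):
        """Fitting after 512 -> 128 Hz decimation changes the exponent by
        less than 0.05 on clean synthetics."""
        rec, _ = make_recording("biosemi_like", alpha_params, seed=21,
                                inject_artifacts=False)
        native = rec.copy()
        # same cleaning, with and without rate reduction
        c1, _ = preprocess_recording(native, target_fs=None)
        f1 = fit_spectrum(welch_psd(c1, "F3", nperseg=4096))
        c2, _ = preprocess_recording(rec, target_fs=128.0)
        f2 = fit_spectrum(welch_psd(c2, "F3"))
        assert abs(f1.exponent - f2.exponent) < 0.05


class TestFitQuality:
    def test_perfect_model(self, analytic_grid):
        ps = analytic_spectrum(SpectralParams(1.0, 1.5), analytic_grid)
        fit = fit_spectrum(ps)
        r2, mae = fit_quality(fit, ps)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert mae == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_gives_mae_delta(self, analytic_grid):
        ps = analytic_spectrum(SpectralParams(1.0, 1.5), analytic_grid)
        fit = fit_spectrum(ps)
        shifted = PowerSpectrum("F3", analytic_grid, ps.power * 10 ** 0.3)
        _, mae = fit_quality(fit, shifted)
        assert mae == pytest.approx(0.3, abs=1e-9)

    def test_realistic_fits_fall_in_plausible_band(self, consumer_recording):
        rec, _ = consumer_recording
        clean, _ = preprocess_recording(rec)
        ps = welch_psd(clean, "F3")
        fit = fit_spectrum(ps)
        r2, _ = fit_quality(fit, ps)
        assert 0.76 <= r2 <= 1.0


class TestComposite:
    def test_simple_average(self, analytic_grid):
        ps = analytic_spectrum(SpectralParams(2.0, 1.0), analytic_grid)
        fit = fit_spectrum(ps)
        comp = aperiodic_composite({"F3": fit, "F4": fit})
        assert comp == pytest.approx(1.5, abs=1e-3)

    def test_grand_mean_equals_mean_of_four_values(self, analytic_grid):
        f3 = fit_spectrum(analytic_spectrum(SpectralParams(1.0, 2.0),
                                            analytic_grid))
        f4 = fit_spectrum(analytic_spectrum(SpectralParams(2.0, 1.0),
                                            analytic_grid))
        comp = aperiodic_composite({"F3": f3, "F4": f4})
        manual = np.mean([f3.offset, f3.exponent, f4.offset, f4.exponent])
        assert comp == pytest.approx(manual, abs=1e-12)

    def test_missing_channel_named_in_error(self, analytic_grid):
        fit = fit_spectrum(analytic_spectrum(SpectralParams(1.0, 1.0),
                                             analytic_grid))
        with pytest.raises(KeyError, match="F3"):
            aperiodic_composite({"F4": fit})
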