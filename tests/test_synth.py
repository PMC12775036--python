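"""Generator tests: device profiles, the analytic spectrum oracle,
spectral fidelity of synthesized recordings, and behavioral calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aperio.profiles import device_profile, registered_profiles
from aperio.spectral import welch_psd
from aperio.synth import (
    Peak,
    SpectralParams,
    draw_half_parameters,
    oracle_psd,
    subject_truth_composite,
    synth_behavior,
    synth_cohort,
    synth_recording,
)
from conftest import make_recording


class TestDeviceProfiles:
    def test_sampling_rates(self):
        assert device_profile("emotiv_like").fs == 128.0
        assert device_profile("biosemi_like").fs == 512.0

    def test_unknown_profile_lists_registered(self):
        with pytest.raises(KeyError, match="emotiv_like"):
            device_profile("unknown")

    def test_consumer_profile_is_noisier(self):
        emo, bio = device_profile("emotiv_like"), device_profile("biosemi_like")
        assert emo.line_noise_amp > bio.line_noise_amp
        assert emo.harmonic_bump_amp > bio.harmonic_bump_amp
        assert emo.drift_amp > bio.drift_amp
        assert emo.artifact_rate > bio.artifact_rate

    def test_frontal_channels_present(self):
        for name in registered_profiles():
            assert {"F3", "F4"} <= set(device_profile(name).channels)


class TestOraclePsd:
    @pytest.mark.parametrize(
        "f, params, expected_log10",
        [
            (1.0, SpectralParams(0.0, 1.0), 0.0),
            (10.0, SpectralParams(1.0, 2.0), -1.0),
            # peak apex adds its height to the aperiodic value
            (10.0, SpectralParams(1.0, 2.0, (Peak(10.0, 0.5, 2.0),)), -0.5),
        ],
    )
    def test_known_points(self, f, params, expected_log10):
        p = oracle_psd(np.array([f]), params)
        assert np.log10(p[0]) == pytest.approx(expected_log10, abs=1e-12)

    def test_rejects_nonpositive_frequencies(self):
        with pytest.raises(ValueError):
            oracle_psd(np.array([0.0, 1.0]), SpectralParams(0.0, 1.0))

    @given(b=st.floats(-2, 2), chi=st.floats(0, 3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_power_positive_and_monotone_for_pure_powerlaw(self, b, chi):
        f = np.array([1.0, 5.0, 20.0, 40.0])
        p = oracle_psd(f, SpectralParams(b, chi))
        assert np.all(p > 0)
        assert np.all(np.diff(p) <= 0)


class TestSynthRecording:
    def test_deterministic_for_fixed_seed(self, alpha_params):
        a, _ = make_recording(seed=3)
        b, _ = make_recording(seed=3)
        assert np.array_equal(a.data, b.data)

    def test_spectral_fidelity_noiseless(self, alpha_params):
        """Welch PSD of a 240 s clean realization tracks the analytic
        target within 0.05 log10 units (median over 1-40 Hz)."""
        rec, _ = make_recording("emotiv_like", alpha_params, seed=5,
                                inject_artifacts=False)
        # strip nuisance terms by synthesizing with a silent profile
        from aperio.profiles import DeviceProfile
        silent = DeviceProfile("silent", 128.0, 0, 0, 0, 0.0)
        rec, _ = synth_recording(
            {c: (alpha_params, alpha_params) for c in silent.channels},
            silent, 240.0, seed=5,
        )
        ps = welch_psd(rec, "F3").band(1, 40)
        dev = np.log10(ps.power) - np.log10(oracle_psd(ps.freqs, alpha_params))
        assert np.median(np.abs(dev)) < 0.05

    def test_line_noise_band_exceeds_neighbour_band(self):
        rec, _ = make_recording("emotiv_like", seed=9, inject_artifacts=False)
        ps = welch_psd(rec, "F3")
        band = lambda lo, hi: np.log10(
            ps.power[(ps.freqs >= lo) & (ps.freqs <= hi)]).mean()
        assert band(49, 51) > band(45, 47)

    def test_burst_mask_flags_high_amplitude_samples(self):
        rec, burst = make_recording("emotiv_like", seed=11)
        assert burst.any()
        assert np.abs(rec.data[:, burst]).max() > 300

    def test_too_short_duration_rejected(self, alpha_params):
        with pytest.raises(ValueError):
            make_recording(duration_s=4.0)


class TestSynthCohort:
    def test_counts_and_truth_shape(self):
        recs, truth = synth_cohort(2, device_profile("emotiv_like"),
                                   duration_s=30.0, seed=0)
        assert len(recs) == 2
        # 2 subjects x 2 channels x 2 halves
        assert len(truth) == 8
        assert set(truth.channel) == {"F3", "F4"}

    def test_same_seed_reproduces_cohort(self):
        a = synth_cohort(3, device_profile("emotiv_like"), 30.0, seed=4)
        b = synth_cohort(3, device_profile("emotiv_like"), 30.0, seed=4)
        for ra, rb in zip(a[0], b[0]):
            assert np.array_equal(ra.data, rb.data)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_subject_streams_stable_under_growth(self):
        small = synth_cohort(2, device_profile("emotiv_like"), 30.0, seed=4)
        large = synth_cohort(4, device_profile("emotiv_like"), 30.0, seed=4)
        assert np.array_equal(small[0][0].data, large[0][0].data)

    def test_exponent_truncation_respected(self):
        truth = draw_half_parameters(
            200, np.random.default_rng(0), {"exponent_mean": 0.3})
        assert (truth.exponent >= 0.3).all()

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            draw_half_parameters(5, np.random.default_rng(0), {"bogus": 1})
        with pytest.raises(ValueError):
            draw_half_parameters(5, np.random.default_rng(0), {"rho_half": 1.5})

    def test_rho_half_sets_cross_half_parameter_correlation(self):
        truth = draw_half_parameters(
            3000, np.random.default_rng(2), {"rho_half": 0.6})
        wide = truth[truth.channel == "F3"].pivot(
            index="subject", columns="half", values="exponent")
        r = np.corrcoef(wide[1], wide[2])[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)


class TestSynthBehavior:
    def test_scores_within_bounds(self, rng):
        beh = synth_behavior(rng.standard_normal(500), target_r=-0.4, seed=1)
        assert beh.math.between(0, 200).all()
        for col in ("wm_verbal", "wm_visuospatial"):
            assert beh[col].between(0, 1).all()

    def test_null_correlation_large_sample(self, rng):
        x = rng.standard_normal(10_000)
        beh = synth_behavior(x, target_r=0.0, seed=2)
        assert abs(np.corrcoef(x, beh.math_raw)[0, 1]) < 0.05

    def test_target_r_recovered_on_average(self, rng):
        """Mean pre-clipping correlation over cohorts of n=90 sits within
        +/-0.02 of the requested population value."""
        rs = []
        for i in range(500):
            x = rng.standard_normal(90)
            beh = synth_behavior(x, target_r=-0.23, seed=int(rng.integers(2**31)))
            rs.append(np.corrcoef(x, beh.math_raw)[0, 1])
        assert np.mean(rs) == pytest.approx(-0.23, abs=0.02)

    def test_requires_three_subjects(self):
        with pytest.raises(ValueError):
            synth_behavior(np.array([1.0, 2.0]), seed=0)
        with pytest.raises(ValueError):
            synth_behavior(np.ones(10) + np.arange(10), target_r=1.0, seed=0)


def test_truth_composite_matches_manual_average():
    recs, truth = synth_cohort(3, device_profile("emotiv_like"), 30.0, seed=6)
    comp = subject_truth_composite(truth)
    s0 = truth[truth.subject == "s000"]
    manual = np.mean([s0[s0.channel == c][p].mean()
                      for c in ("F3", "F4") for p in ("offset", "exponent")])
    assert comp["s000"] == pytest.approx(manual, abs=1e-12)
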