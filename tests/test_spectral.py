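"""Spectral feature contracts: DFT magnitudes, dB view, F0, harmonics."""

import dataclasses

import numpy as np
import pytest

from gaitsep.signal_io import Frame, SignalRecord, TooShortError
from gaitsep.spectral import (
    NoPeriodicityError,
    dft_magnitudes,
    estimate_fundamental,
    feature_columns,
    feature_matrix,
    harmonic_features,
    magnitude_spectrum,
    to_decibels,
)
from gaitsep.synthetic import synthesize_trial


def _frame(window, fs=120.0):
    return Frame(
        subject_id=1, day=1, trial=1, source_name="fle",
        sensor_kind="trajectory", sampling_rate=fs, frame_index=0, window=window,
    )


def brute_force_dft_magnitudes(x):
    """Direct O(N^2) evaluation of the DFT sum, k = 0..N/2."""
    n = len(x)
    ks = np.arange(n // 2 + 1)
    out = np.empty(ks.size)
    for k in ks:
        out[k] = abs(np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n)))
    return out


class TestDftMagnitudes:
    def test_constant_window_is_dc_only(self):
        spec = dft_magnitudes(_frame(np.full(256, 3.0)))
        assert spec.magnitudes[0] == pytest.approx(768.0, abs=1e-9)
        assert np.all(spec.magnitudes[1:] <= 1e-9)
        assert spec.frequencies[0] == 0.0 and spec.frequencies[-1] == 60.0

    def test_single_bin_cosine_has_half_n_magnitude(self):
        n = 256
        window = np.cos(2 * np.pi * 8 * np.arange(n) / n)
        spec = dft_magnitudes(_frame(window))
        assert spec.magnitudes[8] == pytest.approx(128.0, abs=1e-9)
        others = np.delete(spec.magnitudes, 8)
        assert np.all(others <= 1e-9)

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            window = rng.standard_normal(256)
            spec = dft_magnitudes(_frame(window))
            expected = brute_force_dft_magnitudes(window)
            np.testing.assert_allclose(spec.magnitudes, expected, rtol=1e-9, atol=1e-9)

    def test_parseval_identity_on_full_spectrum(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(256)
        full = np.abs(np.fft.fft(x))
        assert np.sum(full**2) == pytest.approx(256 * np.sum(x**2), rel=1e-9)
        # the half-spectrum features agree with the full transform's prefix
        spec = dft_magnitudes(_frame(x))
        np.testing.assert_allclose(spec.magnitudes, full[:129], rtol=1e-12)

    def test_transform_is_linear(self):
        rng = np.random.default_rng(7)
        a, b = rng.standard_normal(256), rng.standard_normal(256)
        fa = np.fft.rfft(a)
        fb = np.fft.rfft(b)
        np.testing.assert_allclose(np.fft.rfft(a + 2 * b), fa + 2 * fb, rtol=1e-9)
        # magnitudes of the summed transform bound by triangle inequality
        spec_sum = dft_magnitudes(_frame(a + b))
        assert np.all(
            spec_sum.magnitudes
            <= dft_magnitudes(_frame(a)).magnitudes
            + dft_magnitudes(_frame(b)).magnitudes
            + 1e-9
        )


class TestDecibels:
    def test_reference_and_scaling(self):
        spec = dft_magnitudes(_frame(np.full(256, 1.0)))
        spec = dataclasses.replace(spec, magnitudes=np.array([1.0, 10.0, 0.0]),
                                   frequencies=np.array([0.0, 1.0, 2.0]))
        db = to_decibels(spec, floor=1e-12)
        assert db.magnitudes[0] == pytest.approx(0.0)
        assert db.magnitudes[1] == pytest.approx(20.0)
        assert db.magnitudes[2] == pytest.approx(-240.0)
        assert db.scale == "dB"

    def test_double_conversion_rejected(self):
        spec = dft_magnitudes(_frame(np.ones(256)))
        with pytest.raises(ValueError, match="dB"):
            to_decibels(to_decibels(spec))


def _sine_record(freq, fs=120.0, duration=10.0, harmonics=()):
    t = np.arange(int(duration * fs)) / fs
    z = np.cos(2 * np.pi * freq * t)
    for mult, amp in harmonics:
        z = z + amp * np.cos(2 * np.pi * mult * freq * t + 0.7)
    return SignalRecord(
        subject_id=1, day=1, trial=1, source_name="fle",
        sensor_kind="trajectory", sampling_rate=fs,
        samples_x=np.zeros_like(z), samples_y=np.zeros_like(z), samples_z=z,
    )


def lag_quantum(f0, fs):
    """Frequency spacing of adjacent autocorrelation lags near f0."""
    lag = fs / f0
    return fs / (lag - 1) - fs / lag


class TestEstimateFundamental:
    def test_pure_tone_recovered_within_one_lag_quantum(self):
        est = estimate_fundamental(_sine_record(1.0), search_band=(0.5, 2.5))
        assert abs(est - 1.0) <= lag_quantum(1.0, 120.0)

    def test_printed_gait_fundamental_recovered(self, clean_profile, trial_spec):
        # the worked example: a 0.94 Hz walking signal with 5 harmonics
        profile = clean_profile(n_harmonics=5, main=30.0, f0=0.94)
        record = synthesize_trial(profile, trial_spec(duration=20.0), seed=3)
        est = estimate_fundamental(record, search_band=(0.5, 2.5))
        assert abs(est - 0.94) <= lag_quantum(0.94, 120.0)

    def test_strong_second_harmonic_does_not_cause_octave_error(self):
        record = _sine_record(0.9, harmonics=((2, 2.5),))
        est = estimate_fundamental(record, search_band=(0.5, 2.5))
        assert abs(est - 0.9) <= lag_quantum(0.9, 120.0)

    def test_matches_exhaustive_lag_scan(self):
        record = _sine_record(1.1, harmonics=((2, 0.8), (3, 0.5)))
        z = record.samples_z - record.samples_z.mean()
        fs = 120.0
        lags = np.arange(int(np.ceil(fs / 2.5)), int(np.floor(fs / 0.5)) + 1)
        scan = [np.dot(z[:-lag], z[lag:]) for lag in lags]
        expected = fs / lags[int(np.argmax(scan))]
        assert estimate_fundamental(record, search_band=(0.5, 2.5)) == expected

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Fs/2"):
            estimate_fundamental(_sine_record(1.0), search_band=(0.5, 80.0))

    def test_too_short_signal_rejected(self):
        with pytest.raises(TooShortError):
            estimate_fundamental(_sine_record(1.0, duration=3.0), search_band=(0.5, 2.5))

    def test_noise_gives_no_periodicity(self):
        rng = np.random.default_rng(0)
        record = _sine_record(1.0)
        record = record.with_axes(
            record.samples_x, record.samples_y, rng.standard_normal(1200)
        )
        with pytest.raises(NoPeriodicityError):
            estimate_fundamental(record, search_band=(0.5, 2.5))

    def test_parameter_recovery_over_seeded_cohort(self, clean_profile, trial_spec):
        # median |error| over many seeded trials stays below one lag quantum
        rng = np.random.default_rng(42)
        errors = []
        for k in range(100):
            f0 = rng.uniform(0.7, 1.2)
            profile = dataclasses.replace(
                clean_profile(n_harmonics=4, main=25.0), f0_mean=f0, noise_sd=0.5
            )
            record = synthesize_trial(profile, trial_spec(duration=15.0), seed=k)
            est = estimate_fundamental(record, search_band=(0.5, 2.5))
            errors.append(abs(est - f0) / lag_quantum(f0, 120.0))
        assert np.median(errors) < 1.0


class TestHarmonicFeatures:
    def test_single_bin_cosine_maps_to_first_harmonic(self):
        n = 256
        fs = 120.0
        window = np.cos(2 * np.pi * 8 * np.arange(n) / n)
        spec = dft_magnitudes(_frame(window))
        f0 = 8 * fs / n
        hf = harmonic_features(spec, f0, n_harmonics=6)
        assert hf.harmonic_mags[0] == pytest.approx(128.0, abs=1e-9)
        assert np.all(hf.harmonic_mags[1:] <= 1e-6)
        assert hf.as_vector().shape == (7,)
        assert hf.as_vector()[0] == f0

    def test_noise_free_trial_recovers_generator_magnitudes(self, clean_profile, trial_spec):
        # full-trial window, f0 exactly on a bin: |X| at m*f0 = (N/2) * a_m
        profile = clean_profile(n_harmonics=5, main=12.0, f0=1.0, decay=0.5)
        record = synthesize_trial(profile, trial_spec(duration=50.0), seed=0)
        spec = magnitude_spectrum(record)
        hf = harmonic_features(spec, 1.0, n_harmonics=5)
        n = record.n_samples
        np.testing.assert_allclose(
            hf.harmonic_mags, (n / 2) * profile.harmonic_mags, rtol=1e-6
        )

    def test_third_harmonic_of_printed_fundamental_queried_at_2_82_hz(self):
        spec = dft_magnitudes(_frame(np.ones(256)))
        hf_band = 3 * 0.94
        assert hf_band == pytest.approx(2.82)
        # nearest-bin lookup window for m=3 is centred on 2.82 Hz
        k = int(round(hf_band / spec.bin_width))
        assert abs(spec.frequencies[k] - 2.82) <= spec.bin_width / 2

    def test_harmonic_above_nyquist_rejected(self):
        spec = dft_magnitudes(_frame(np.ones(256)))
        with pytest.raises(ValueError, match="harmonic 6"):
            harmonic_features(spec, 10.0, n_harmonics=10)


class TestFeatureMatrix:
    def test_dft_table_shape_and_provenance(self, dc_fixture):
        table = feature_matrix(dc_fixture.records[:2])
        assert list(table.columns[:5]) == [
            "subject_id", "day", "trial", "source", "frame_index"
        ]
        assert len(feature_columns(table)) == 129
        # 15 s at 120 Hz -> 1800 samples -> 25 frames per trial
        assert (table.groupby(["subject_id", "day", "trial"]).size() == 25).all()

    def test_harmonics_table_has_eleven_features(self, dc_fixture):
        table = feature_matrix(dc_fixture.records[:1], feature="harmonics")
        assert feature_columns(table) == [
            "f0", "h01", "h02", "h03", "h04", "h05",
            "h06", "h07", "h08", "h09", "h10",
        ]
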