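"""Generator contracts: cohort identity, spectral placement, determinism, I/O."""

import numpy as np
import pytest

from gaitsep.signal_io import read_session
from gaitsep.spectral import magnitude_spectrum, spectral_peaks
from gaitsep.synthetic import (
    CohortError,
    F0_MAX,
    F0_MIN,
    GeneratorConfig,
    SubjectProfile,
    TrialSpec,
    identity_vector,
    make_cohort,
    standard_plan,
    synthesize_trial,
    write_dataset,
)


class TestMakeCohort:
    def test_profiles_respect_physiological_f0_band(self):
        cohort = make_cohort(25, seed=7)
        assert len(cohort) == 25
        assert all(F0_MIN <= p.f0_mean <= F0_MAX for p in cohort)

    def test_same_seed_reproduces_cohort(self):
        a = make_cohort(2, seed=1)
        b = make_cohort(2, seed=1)
        for pa, pb in zip(a, b):
            assert pa.traj_dc == pb.traj_dc
            assert np.array_equal(pa.harmonic_mags, pb.harmonic_mags)
            assert np.array_equal(pa.idband_freqs, pb.idband_freqs)

    def test_every_pair_of_subjects_differs_in_identity_channels(self):
        cohort = make_cohort(25, seed=7)
        vectors = [identity_vector(p) for p in cohort]
        for i in range(len(vectors)):
            for j in range(i + 1, len(vectors)):
                assert np.linalg.norm(vectors[i] - vectors[j]) > 0

    def test_single_subject_rejected(self):
        with pytest.raises(CohortError):
            make_cohort(1, seed=0)


class TestSubjectProfileInvariants:
    def test_f0_outside_band_rejected(self, clean_profile):
        with pytest.raises(ValueError, match="f0_mean"):
            clean_profile(f0=1.4)

    def test_idband_frequency_outside_band_rejected(self):
        with pytest.raises(ValueError, match="idband"):
            SubjectProfile(
                subject_id=1, traj_dc=400.0, accel_dc=9.8, f0_mean=1.0,
                f0_trial_jitter_sd=0.0, harmonic_mags=[10.0],
                harmonic_phases=[0.0], idband_freqs=[4.0], idband_mags=[1.0],
                noise_sd=0.0,
            )

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SubjectProfile(
                subject_id=1, traj_dc=400.0, accel_dc=9.8, f0_mean=1.0,
                f0_trial_jitter_sd=0.0, harmonic_mags=[-1.0],
                harmonic_phases=[0.0], idband_freqs=[], idband_mags=[],
                noise_sd=0.0,
            )


class TestSynthesizeTrial:
    def test_noise_free_single_harmonic_is_shifted_cosine(self, clean_profile, trial_spec):
        # z[n] = dc + a*cos(2 pi f0 n/Fs + phi) for some phase phi
        profile = clean_profile(n_harmonics=1, main=10.0, f0=1.0, dc=400.0)
        record = synthesize_trial(profile, trial_spec(), seed=5)
        z = record.samples_z
        t = np.arange(z.size) / 120.0
        # recover the phase by least squares and compare against closed form
        design = np.column_stack(
            [np.cos(2 * np.pi * t), np.sin(2 * np.pi * t), np.ones_like(t)]
        )
        coef, *_ = np.linalg.lstsq(design, z, rcond=None)
        assert np.hypot(coef[0], coef[1]) == pytest.approx(10.0, rel=1e-9)
        assert coef[2] == pytest.approx(400.0, rel=1e-9)
        phi = np.arctan2(-coef[1], coef[0])
        np.testing.assert_allclose(
            z, 400.0 + 10.0 * np.cos(2 * np.pi * t + phi), atol=1e-8
        )

    def test_same_seed_reproduces_samples(self, clean_profile, trial_spec):
        profile = clean_profile(n_harmonics=3)
        a = synthesize_trial(profile, trial_spec(), seed=9)
        b = synthesize_trial(profile, trial_spec(), seed=9)
        np.testing.assert_array_equal(a.samples_z, b.samples_z)
        np.testing.assert_array_equal(a.samples_x, b.samples_x)

    def test_noise_free_dft_peaks_sit_on_harmonics(self, clean_profile, trial_spec):
        # 50 s at 120 Hz -> 0.02 Hz bins; f0 = 1.0 falls exactly on a bin
        profile = clean_profile(n_harmonics=5, main=10.0, f0=1.0)
        record = synthesize_trial(profile, trial_spec(duration=50.0), seed=2)
        peaks = spectral_peaks(magnitude_spectrum(record))
        np.testing.assert_allclose(peaks, [1.0, 2.0, 3.0, 4.0, 5.0], atol=1e-9)

    def test_spectral_energy_confined_to_declared_components(self, trial_spec):
        profile = SubjectProfile(
            subject_id=1, traj_dc=450.0, accel_dc=9.8, f0_mean=1.0,
            f0_trial_jitter_sd=0.0, harmonic_mags=[20.0, 8.0],
            harmonic_phases=[0.3, 1.1], idband_freqs=[7.0, 9.0],
            idband_mags=[2.0, 1.0], noise_sd=0.0,
        )
        record = synthesize_trial(profile, trial_spec(duration=50.0), seed=4)
        spec = magnitude_spectrum(record)
        expected_bins = {
            int(round(f / spec.bin_width)) for f in (1.0, 2.0, 7.0, 9.0)
        }
        off_peak = np.delete(spec.magnitudes[1:], [k - 1 for k in expected_bins])
        assert off_peak.sum() < 1e-6 * spec.magnitudes[1:].max()

    def test_increasing_dc_separation_increases_dc_feature_distance(
        self, clean_profile, trial_spec
    ):
        import dataclasses

        from gaitsep.signal_io import frame_signal
        from gaitsep.spectral import dft_magnitudes

        base = clean_profile(n_harmonics=3, dc=450.0)
        distances = []
        for delta in (5.0, 15.0, 40.0):
            other = dataclasses.replace(base, traj_dc=450.0 + delta)
            fa = frame_signal(synthesize_trial(base, trial_spec(), seed=1))[0]
            fb = frame_signal(synthesize_trial(other, trial_spec(), seed=1))[0]
            distances.append(
                abs(dft_magnitudes(fa).magnitudes[0] - dft_magnitudes(fb).magnitudes[0])
            )
        assert distances[0] < distances[1] < distances[2]

    def test_acceleration_trial_uses_gravity_dc(self, clean_profile, trial_spec):
        profile = clean_profile(n_harmonics=1)
        record = synthesize_trial(
            profile, trial_spec(sensor_kind="acceleration", source_name="mcu"), seed=1
        )
        assert record.samples_z.mean() == pytest.approx(9.80665, abs=0.05)

    def test_invalid_trial_spec_rejected(self):
        with pytest.raises(ValueError, match="256"):
            TrialSpec(day=1, trial_index=1, duration=1.0, sampling_rate=120.0)
        with pytest.raises(ValueError, match="20 Hz"):
            TrialSpec(day=1, trial_index=1, duration=60.0, sampling_rate=15.0)


class TestWriteDataset:
    def test_one_file_per_subject_day_trial_source(self, tmp_path):
        cohort = make_cohort(2, seed=0)
        plan = standard_plan(days=2, trials_per_day=2, duration=3.0)
        paths = write_dataset(cohort, plan, tmp_path, seed=0)
        assert len(paths) == 2 * 2 * 2 * 1
        assert all(p.exists() for p in paths)

    def test_round_trip_preserves_samples(self, tmp_path):
        cohort = make_cohort(2, seed=0)
        plan = standard_plan(days=1, trials_per_day=1, duration=3.0)
        from gaitsep.synthetic import synthesize_cohort

        originals = synthesize_cohort(cohort, plan, seed=0)
        paths = write_dataset(cohort, plan, tmp_path, seed=0)
        for original, path in zip(originals, sorted(paths)):
            loaded = read_session(path)
            assert loaded.subject_id == original.subject_id
            assert loaded.sampling_rate == original.sampling_rate
            for axis in ("samples_x", "samples_y", "samples_z"):
                np.testing.assert_allclose(
                    getattr(loaded, axis), getattr(original, axis), atol=1e-9
                )

    def test_empty_trial_plan_writes_nothing(self, tmp_path):
        cohort = make_cohort(2, seed=0)
        assert write_dataset(cohort, [], tmp_path, seed=0) == []
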