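"""Shared fixtures: small seeded cohorts with identity in known channels."""

import numpy as np
import pytest

from gaitsep.pipeline import fixture_cohort
from gaitsep.synthetic import SubjectProfile, TrialSpec


@pytest.fixture(scope="session")
def dc_fixture():
    return fixture_cohort("dc_identity", n_subjects=6, seed=3)


@pytest.fixture(scope="session")
def band_fixture():
    return fixture_cohort("band_identity", n_subjects=6, seed=3)


@pytest.fixture(scope="session")
def null_fixture():
    return fixture_cohort("null", n_subjects=4, seed=3)


@pytest.fixture
def clean_profile():
    """Noise-free single-harmonic subject for closed-form checks."""

    def build(n_harmonics=1, main=10.0, f0=1.0, dc=400.0, phases=None, decay=0.6):
        mags = main * decay ** np.arange(n_harmonics)
        return SubjectProfile(
            subject_id=1,
            traj_dc=dc,
            accel_dc=9.80665,
            f0_mean=f0,
            f0_trial_jitter_sd=0.0,
            harmonic_mags=mags,
            harmonic_phases=np.zeros(n_harmonics) if phases is None else phases,
            idband_freqs=np.empty(0),
            idband_mags=np.empty(0),
            noise_sd=0.0,
        )

    return build


@pytest.fixture
def trial_spec():
    def build(duration=10.0, sampling_rate=120.0, **kwargs):
        defaults = dict(day=1, trial_index=1)
        defaults.update(kwargs)
        return TrialSpec(duration=duration, sampling_rate=sampling_rate, **defaults)

    return build
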