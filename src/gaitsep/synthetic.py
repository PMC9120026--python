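"""Synthetic multi-subject walking-signal generator.

Each subject is a :class:`SubjectProfile`: a DC offset (marker height for
trajectories, gravity for accelerations), a gait fundamental frequency near
1 Hz with a decaying harmonic series (gait cycle, steps, flexion/extension
events), a handful of small periodic components in the 6-10 Hz band (the
intra-harmonic identity band: muscle vibration, impact transients), and
broadband measurement noise concentrated above 10 Hz.  Identity information
is therefore injected into controllable spectral channels — DC, harmonic
magnitude profile, and the 6-10 Hz band — so downstream ablations can switch
each channel off and observe the effect on subject separability.

The generator is *not* a biomechanical gait simulator; it reproduces only
the spectral structure of vertical leg-marker trajectories and thigh
accelerations that the analysis pipeline consumes.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as _sps

from .signal_io import SignalRecord, filename_for, write_session

#: physiological bounds on the gait-cycle (fundamental) frequency, Hz.
#: People step at up to ~2.5 Hz, so full cycles repeat at up to ~1.25 Hz.
F0_MIN, F0_MAX = 0.5, 1.25

#: the intra-harmonic identity band, Hz
IDBAND = (6.0, 10.0)

STANDARD_GRAVITY = 9.80665  # m/s^2

#: ratio of accelerometer broadband-noise scale (m/s^2) to trajectory
#: noise scale (mm) — MCU accelerometers are noisier than optical capture
ACCEL_NOISE_FACTOR = 0.4


class CohortError(ValueError):
    """Invalid cohort request."""


@dataclasses.dataclass
class SubjectProfile:
    """Generative parameters that constitute one synthetic subject's identity.

    Parameters
    ----------
    traj_dc
        Vertical trajectory offset in mm (marker height; body-length proxy).
    accel_dc
        Constant acceleration offset in m/s^2 (gravity analogue; identical
        across subjects by default, carrying no identity).
    f0_mean, f0_trial_jitter_sd
        Subject's typical gait-cycle frequency (Hz) and its trial-to-trial
        standard deviation.
    harmonic_mags, harmonic_phases
        Relative magnitudes (mm) and phases of harmonics m=1..M at m*f0.
    idband_freqs, idband_mags
        Frequencies (within 6-10 Hz) and magnitudes (mm, small relative to
        the harmonics) of the subject's intra-harmonic components.
    noise_sd
        Broadband noise scale (mm); the noise is high-passed at 10 Hz so
        its energy sits above the identity band.
    """

    subject_id: int
    traj_dc: float
    accel_dc: float
    f0_mean: float
    f0_trial_jitter_sd: float
    harmonic_mags: np.ndarray
    harmonic_phases: np.ndarray
    idband_freqs: np.ndarray
    idband_mags: np.ndarray
    noise_sd: float

    def __post_init__(self) -> None:
        self.harmonic_mags = np.asarray(self.harmonic_mags, dtype=float)
        self.harmonic_phases = np.asarray(self.harmonic_phases, dtype=float)
        self.idband_freqs = np.asarray(self.idband_freqs, dtype=float)
        self.idband_mags = np.asarray(self.idband_mags, dtype=float)
        if not F0_MIN <= self.f0_mean <= F0_MAX:
            raise ValueError(
                f"f0_mean={self.f0_mean} outside the physiological band "
                f"[{F0_MIN}, {F0_MAX}] Hz"
            )
        if self.traj_dc <= 0:
            raise ValueError("traj_dc must be positive")
        if self.harmonic_mags.size != self.harmonic_phases.size:
            raise ValueError("harmonic_mags and harmonic_phases lengths differ")
        if self.idband_freqs.size != self.idband_mags.size:
            raise ValueError("idband_freqs and idband_mags lengths differ")
        if np.any(self.harmonic_mags < 0) or np.any(self.idband_mags < 0):
            raise ValueError("magnitudes must be nonnegative")
        if self.noise_sd < 0 or self.f0_trial_jitter_sd < 0:
            raise ValueError("scales must be nonnegative")
        if self.idband_freqs.size and (
            np.any(self.idband_freqs < IDBAND[0]) or np.any(self.idband_freqs > IDBAND[1])
        ):
            raise ValueError(f"idband frequencies must lie in {IDBAND} Hz")


@dataclasses.dataclass
class TrialSpec:
    """One trial to synthesize: day, index, duration and acquisition settings."""

    day: int
    trial_index: int
    duration: float
    sampling_rate: float = 120.0
    sensor_kind: str = "trajectory"
    source_name: str = "fle"

    def __post_init__(self) -> None:
        if self.day not in (1, 2):
            raise ValueError("day must be 1 or 2")
        if self.trial_index < 1:
            raise ValueError("trial_index starts at 1")
        if self.sampling_rate <= 20.0:
            raise ValueError("sampling_rate must exceed 20 Hz (Nyquist above 10 Hz)")
        if self.duration * self.sampling_rate < 256:
            raise ValueError("trial must contain at least one 256-sample frame")
        if self.sensor_kind not in ("trajectory", "acceleration"):
            raise ValueError(f"unknown sensor_kind {self.sensor_kind!r}")


@dataclasses.dataclass
class GeneratorConfig:
    """Cohort-level distributions from which subject identities are drawn."""

    traj_dc_range: tuple = (420.0, 560.0)  # mm, knee-height landmark span
    accel_dc: float = STANDARD_GRAVITY
    f0_range: tuple = (0.8, 1.2)  # Hz
    f0_trial_jitter_sd: float = 0.02  # Hz
    n_harmonics: int = 10
    main_amplitude_mean: float = 30.0  # mm -> ~60 mm peak-to-peak main cycle
    main_amplitude_sd: float = 3.0
    harmonic_decay: float = 0.55  # geometric decay per harmonic (see methods)
    harmonic_jitter_sd: float = 0.15  # lognormal sigma on each harmonic
    n_idband: int = 2
    idband_mag_range: tuple = (1.0, 2.0)  # mm -> ~2-4 mm peak-to-peak
    noise_sd: float = 0.5  # mm


def make_cohort(
    n_subjects: int, config: GeneratorConfig | None = None, seed: int = 0
) -> list[SubjectProfile]:
    """Draw ``n_subjects`` distinct subject identities.

    Deterministic given ``seed``.  Requires at least two subjects because
    the downstream pairing stage needs different-subject pairs.
    """
    if n_subjects < 2:
        raise CohortError("a cohort needs at least 2 subjects (pairing requires it)")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    m_idx = np.arange(cfg.n_harmonics)
    profiles = []
    for sid in range(1, n_subjects + 1):
        main = max(5.0, rng.normal(cfg.main_amplitude_mean, cfg.main_amplitude_sd))
        mags = main * cfg.harmonic_decay**m_idx
        mags = mags * np.exp(rng.normal(0.0, cfg.harmonic_jitter_sd, cfg.n_harmonics))
        profiles.append(
            SubjectProfile(
                subject_id=sid,
                traj_dc=rng.uniform(*cfg.traj_dc_range),
                accel_dc=cfg.accel_dc,
                f0_mean=rng.uniform(*cfg.f0_range),
                f0_trial_jitter_sd=cfg.f0_trial_jitter_sd,
                harmonic_mags=mags,
                harmonic_phases=rng.uniform(0.0, 2.0 * np.pi, cfg.n_harmonics),
                idband_freqs=np.sort(rng.uniform(*IDBAND, cfg.n_idband)),
                idband_mags=rng.uniform(*cfg.idband_mag_range, cfg.n_idband),
                noise_sd=cfg.noise_sd,
            )
        )
    return profiles


def identity_vector(profile: SubjectProfile) -> np.ndarray:
    """Flat vector of a profile's identity channels (DC, harmonics, id band)."""
    return np.concatenate(
        [
            [profile.traj_dc],
            profile.harmonic_mags,
            profile.idband_freqs,
            profile.idband_mags,
        ]
    )


def _accel_amplitude(traj_amp_mm: float, freq_hz: float) -> float:
    # a cosine displacement of amplitude A has acceleration amplitude A*(2*pi*f)^2
    return traj_amp_mm * (2.0 * np.pi * freq_hz) ** 2 / 1000.0


def _trial_rng(profile: SubjectProfile, spec: TrialSpec, seed: int) -> np.random.Generator:
    tag = zlib.crc32(f"{spec.source_name}:{spec.sensor_kind}".encode())
    return np.random.default_rng(
        [int(seed), int(profile.subject_id), int(spec.day), int(spec.trial_index), tag]
    )


def synthesize_trial(
    profile: SubjectProfile,
    spec: TrialSpec,
    seed: int = 0,
    phase_jitter_sd: float = 0.1,
) -> SignalRecord:
    """Render one trial of one subject as a three-axis record.

    The z axis carries the identity structure:

    ``z[n] = dc + sum_m a_m cos(2 pi m f0 (t+tau) + phi_m + eps_m)
            + sum_b b cos(2 pi f_b t + psi_b) + noise``

    with the per-trial fundamental ``f0 ~ N(f0_mean, f0_trial_jitter_sd)``
    clipped to the physiological band, a random trial time offset ``tau`` and
    small per-component phase jitter so same-subject trials from different
    days are similar but never identical.  Acceleration trials replace the
    trajectory DC by gravity and scale each cosine by ``(2 pi f)^2 / 1000``.
    The x/y axes are low-amplitude correlates kept only for file-format
    completeness; analysis consumes z.
    """
    rng = _trial_rng(profile, spec, seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    nyquist = fs / 2.0

    f0 = float(
        np.clip(rng.normal(profile.f0_mean, profile.f0_trial_jitter_sd), F0_MIN, F0_MAX)
    )
    tau = rng.uniform(0.0, 1.0 / f0)
    accel = spec.sensor_kind == "acceleration"
    dc = profile.accel_dc if accel else profile.traj_dc

    z = np.full(n, dc, dtype=float)
    for m, (amp, phase) in enumerate(
        zip(profile.harmonic_mags, profile.harmonic_phases), start=1
    ):
        freq = m * f0
        jitter = rng.normal(0.0, phase_jitter_sd) if phase_jitter_sd > 0 else 0.0
        if freq >= nyquist or amp == 0.0:
            continue
        a = _accel_amplitude(amp, freq) if accel else amp
        z += a * np.cos(2.0 * np.pi * freq * (t + tau) + phase + jitter)
    for freq, amp in zip(profile.idband_freqs, profile.idband_mags):
        psi = rng.uniform(0.0, 2.0 * np.pi)
        if freq >= nyquist or amp == 0.0:
            continue
        a = _accel_amplitude(amp, freq) if accel else amp
        z += a * np.cos(2.0 * np.pi * freq * t + psi)

    noise_sd = profile.noise_sd * (ACCEL_NOISE_FACTOR if accel else 1.0)
    if noise_sd > 0:
        white = rng.standard_normal(n)
        if nyquist > 10.0:
            sos = _sps.butter(4, 10.0, btype="highpass", fs=fs, output="sos")
            white = _sps.sosfilt(sos, white)
        scale = np.std(white)
        z += white * (noise_sd / scale if scale > 0 else 0.0)

    if accel:
        x = 0.2 * (z - dc) + 0.05 * rng.standard_normal(n)
        y = 0.3 * (z - dc) + 0.05 * rng.standard_normal(n)
    else:
        # x: forward displacement at a plausible walking speed; y: lateral sway
        x = 1250.0 * f0 * t + rng.standard_normal(n)
        y = 0.25 * (z - dc) + rng.standard_normal(n)

    return SignalRecord(
        subject_id=profile.subject_id,
        day=spec.day,
        trial=spec.trial_index,
        source_name=spec.source_name,
        sensor_kind=spec.sensor_kind,
        sampling_rate=fs,
        samples_x=x,
        samples_y=y,
        samples_z=z,
    )


def standard_plan(
    days: int = 2,
    trials_per_day: int = 2,
    duration: float = 20.0,
    sampling_rate: float = 120.0,
    sources: Sequence[tuple[str, str]] = (("fle", "trajectory"),),
) -> list[TrialSpec]:
    """Cross product of days x trials x sources as a list of TrialSpec."""
    return [
        TrialSpec(
            day=d,
            trial_index=k,
            duration=duration,
            sampling_rate=sampling_rate,
            sensor_kind=kind,
            source_name=name,
        )
        for d in range(1, days + 1)
        for k in range(1, trials_per_day + 1)
        for name, kind in sources
    ]


def synthesize_cohort(
    cohort: Sequence[SubjectProfile], trial_plan: Sequence[TrialSpec], seed: int = 0
) -> list[SignalRecord]:
    """Render every (subject, trial) combination in memory."""
    return [
        synthesize_trial(profile, spec, seed=seed)
        for profile in cohort
        for spec in trial_plan
    ]


def write_dataset(
    cohort: Sequence[SubjectProfile],
    trial_plan: Sequence[TrialSpec],
    out_dir,
    seed: int = 0,
) -> list[Path]:
    """Write one session file per (subject, day, trial, source) to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for record in synthesize_cohort(cohort, trial_plan, seed=seed):
        target = out_dir / filename_for(record)
        try:
            write_session(record, target)
        except OSError as exc:
            raise OSError(f"failed writing session file {target}: {exc}") from exc
        paths.append(target)
    return paths
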