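"""Experiment configuration, fixture cohorts and analytic frequency bounds."""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path

import numpy as np
import yaml

from .signal_io import read_cohort
from .synthetic import (
    IDBAND,
    GeneratorConfig,
    SubjectProfile,
    make_cohort,
    standard_plan,
    synthesize_cohort,
    write_dataset,
)

FIXTURE_PROFILES = ("dc_identity", "band_identity", "harmonics_identity", "null")


def derive_frequency_bounds(
    stepping_freq_max: float, exchanges_per_cycle: int
) -> tuple[float, float]:
    """Upper frequency bounds of gait-cycle content from the stepping rate.

    A gait cycle spans two steps, so the maximum cycle frequency is half the
    maximum stepping frequency (~2.5 Hz stepping -> 1.25 Hz cycles).  Knee
    flexion/extension exchanges happen ``exchanges_per_cycle`` times per
    cycle (four for the knee), bounding gait-event content at
    ``exchanges_per_cycle * cycle_freq_max`` (~5 Hz).
    """
    if stepping_freq_max <= 0 or exchanges_per_cycle <= 0:
        raise ValueError("both inputs must be positive")
    cycle_freq_max = stepping_freq_max / 2.0
    return cycle_freq_max, exchanges_per_cycle * cycle_freq_max


@dataclasses.dataclass
class FixtureCohort:
    """A small seeded cohort whose identity lives in one known channel."""

    name: str
    profiles: list
    records: list
    paths: list


def fixture_cohort(
    profile_name: str,
    n_subjects: int = 4,
    trials_per_day: int = 2,
    duration: float = 15.0,
    sampling_rate: float = 120.0,
    sensor_kind: str = "trajectory",
    source: str = "fle",
    seed: int = 0,
    out_dir=None,
) -> FixtureCohort:
    """Mini dataset with identity confined to a single named channel.

    ``dc_identity``: subjects differ only in trajectory DC offset.
    ``band_identity``: only in their 6-10 Hz components.
    ``harmonics_identity``: only in their harmonic magnitude profile.
    ``null``: identical profiles — a negative control with no identity at all.
    """
    if profile_name not in FIXTURE_PROFILES:
        raise ValueError(
            f"unknown fixture profile {profile_name!r}; known: {FIXTURE_PROFILES}"
        )
    if not 2 <= n_subjects <= 6:
        raise ValueError("fixture cohorts hold 2-6 subjects")
    rng = np.random.default_rng([int(seed), zlib.crc32(profile_name.encode())])
    n_harm = 10
    shared_phases = rng.uniform(0.0, 2.0 * np.pi, n_harm)
    shared_mags = 30.0 * 0.55 ** np.arange(n_harm)
    profiles = []
    for i in range(n_subjects):
        dc = 480.0
        mags = shared_mags
        idf = np.empty(0)
        idm = np.empty(0)
        if profile_name == "dc_identity":
            dc = 430.0 + 28.0 * i
        elif profile_name == "band_identity":
            idf = np.sort(rng.uniform(*IDBAND, 2))
            idm = rng.uniform(2.0, 3.0, 2)
        elif profile_name == "harmonics_identity":
            mags = 30.0 * (0.45 + 0.08 * i) ** np.arange(n_harm)
        profiles.append(
            SubjectProfile(
                subject_id=i + 1,
                traj_dc=dc,
                accel_dc=9.80665,
                f0_mean=0.95,
                f0_trial_jitter_sd=0.02,
                harmonic_mags=mags,
                harmonic_phases=shared_phases,
                idband_freqs=idf,
                idband_mags=idm,
                noise_sd=0.5,
            )
        )
    plan = standard_plan(
        days=2,
        trials_per_day=trials_per_day,
        duration=duration,
        sampling_rate=sampling_rate,
        sources=((source, sensor_kind),),
    )
    records = synthesize_cohort(profiles, plan, seed=seed)
    paths = []
    if out_dir is not None:
        paths = write_dataset(profiles, plan, out_dir, seed=seed)
    return FixtureCohort(profile_name, profiles, records, paths)


def benchmark_records(
    seed: int = 0,
    n_subjects: int = 25,
    trials_per_day: int = 4,
    duration: float = 20.0,
    sources=(("fle", "trajectory"),),
    config: GeneratorConfig | None = None,
):
    """The default synthetic benchmark: a full cohort rendered in memory.

    Mirrors the real study's layout (25 subjects, two acquisition days) at a
    desk-scale trial count, with identity present in all three channels.
    """
    cohort = make_cohort(n_subjects, config=config, seed=seed)
    plan = standard_plan(
        days=2, trials_per_day=trials_per_day, duration=duration, sources=sources
    )
    return cohort, synthesize_cohort(cohort, plan, seed=seed)


@dataclasses.dataclass
class ExperimentConfig:
    """Full description of one experiment grid run.

    ``sources`` lists (name, sensor_kind) pairs; ``filter_variants`` are
    names from :func:`gaitsep.filters.filter_bank`; ``modes`` is any subset
    of {identification, verification}.  If ``dataset_dir`` is set, session
    files are read from disk instead of synthesized; otherwise ``fixture``
    (a named fixture profile) or the cohort parameters drive the generator.
    """

    sources: tuple = (("fle", "trajectory"),)
    filter_variants: tuple = ("raw", "notch")
    modes: tuple = ("identification",)
    feature_kind: str = "dft"
    n_subjects: int = 6
    trials_per_day: int = 4
    duration: float = 15.0
    sampling_rate: float = 120.0
    fixture: str | None = None
    dataset_dir: str | None = None
    n_train: int | None = None
    pairs_per_class: int = 500
    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"
    seed: int = 42

    def __post_init__(self) -> None:
        self.sources = tuple((str(n), str(k)) for n, k in self.sources)
        self.filter_variants = tuple(self.filter_variants)
        self.modes = tuple(self.modes)
        for mode in self.modes:
            if mode not in ("identification", "verification"):
                raise ValueError(f"unknown mode {mode!r}")
        if self.feature_kind not in ("dft", "harmonics"):
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)}")
        if "sources" in raw:
            raw["sources"] = tuple(tuple(s) for s in raw["sources"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["sources"] = [list(s) for s in self.sources]
        data["filter_variants"] = list(self.filter_variants)
        data["modes"] = list(self.modes)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def materialize_records(config: ExperimentConfig) -> list:
    """Load or synthesize the records an experiment config refers to."""
    if config.dataset_dir is not None:
        records = read_cohort(config.dataset_dir)
        if not records:
            raise FileNotFoundError(
                f"no session files found under {config.dataset_dir}"
            )
        return records
    if config.fixture is not None:
        return fixture_cohort(
            config.fixture,
            n_subjects=config.n_subjects,
            trials_per_day=config.trials_per_day,
            duration=config.duration,
            sampling_rate=config.sampling_rate,
            seed=config.seed,
        ).records
    cohort = make_cohort(config.n_subjects, seed=config.seed)
    plan = standard_plan(
        days=2,
        trials_per_day=config.trials_per_day,
        duration=config.duration,
        sampling_rate=config.sampling_rate,
        sources=config.sources,
    )
    return synthesize_cohort(cohort, plan, seed=config.seed)
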