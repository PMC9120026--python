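"""DFT-magnitude features, fundamental-frequency estimation, harmonic features.

The per-frame feature vector is the magnitude of the nonnegative-frequency
half of the frame's DFT,

    X[k] = sum_{n=0}^{N-1} x[n] exp(-i 2 pi k n / N),    k = 0 .. N/2,

unnormalized (no 1/N factor), i.e. 129 values for the standard 256-sample
frame.  k = 0 is the DC term (N times the window mean): for trajectories it
encodes marker height, for accelerations gravity.  Harmonic feature vectors
hold the gait fundamental plus the magnitudes at its first harmonics; the
fundamental itself is estimated from the signal's autocorrelation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import signal as _sps

from .signal_io import (
    FRAME_LENGTH,
    FRAME_OVERLAP,
    Frame,
    SignalRecord,
    TooShortError,
    frame_signal,
)

#: provenance columns used by every exported feature table
PROVENANCE_COLUMNS = ("subject_id", "day", "trial", "source", "frame_index")

#: default search band for the gait fundamental, Hz
DEFAULT_F0_BAND = (0.5, 2.5)

DB_FLOOR = 1e-12


class NoPeriodicityError(ValueError):
    """No autocorrelation peak above the voicing threshold in the search band."""


@dataclasses.dataclass
class SpectrumFeature:
    """Nonnegative-frequency DFT magnitudes of one frame (or whole trial)."""

    subject_id: int
    day: int
    trial: int
    source_name: str
    frame_index: int
    sampling_rate: float
    frequencies: np.ndarray
    magnitudes: np.ndarray
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.frequencies.size != self.magnitudes.size:
            raise ValueError("frequencies and magnitudes lengths differ")
        if np.any(np.diff(self.frequencies) <= 0) or self.frequencies[0] != 0.0:
            raise ValueError("frequencies must increase strictly from 0")
        if self.scale == "linear" and np.any(self.magnitudes < 0):
            raise ValueError("linear-scale magnitudes must be nonnegative")

    @property
    def bin_width(self) -> float:
        return float(self.frequencies[1])


@dataclasses.dataclass
class HarmonicFeature:
    """Gait fundamental plus magnitudes at its first ``n`` harmonics."""

    subject_id: int
    day: int
    trial: int
    source_name: str
    frame_index: int
    fundamental: float
    harmonic_mags: np.ndarray

    def __post_init__(self) -> None:
        self.harmonic_mags = np.asarray(self.harmonic_mags, dtype=float)
        if self.fundamental <= 0:
            raise ValueError("fundamental must be positive")

    def as_vector(self) -> np.ndarray:
        """11-dimensional feature: the fundamental followed by 10 magnitudes."""
        return np.concatenate([[self.fundamental], self.harmonic_mags])


def dft_magnitudes(frame: Frame) -> SpectrumFeature:
    """Unnormalized half-spectrum magnitudes |X[k]|, k = 0 .. N/2."""
    n = frame.window.size
    if n % 2:
        raise ValueError("frame length must be even for the half-spectrum layout")
    mags = np.abs(np.fft.rfft(frame.window))
    freqs = np.fft.rfftfreq(n, d=1.0 / frame.sampling_rate)
    return SpectrumFeature(
        subject_id=frame.subject_id,
        day=frame.day,
        trial=frame.trial,
        source_name=frame.source_name,
        frame_index=frame.frame_index,
        sampling_rate=frame.sampling_rate,
        frequencies=freqs,
        magnitudes=mags,
    )


def magnitude_spectrum(record: SignalRecord) -> SpectrumFeature:
    """Half-spectrum magnitudes of a whole trial (one N = L window).

    An odd-length trial is trimmed by one trailing sample so the
    half-spectrum layout (k = 0 .. N/2) applies.
    """
    z = record.samples_z
    if z.size % 2:
        z = z[:-1]
    frame = Frame(
        subject_id=record.subject_id,
        day=record.day,
        trial=record.trial,
        source_name=record.source_name,
        sensor_kind=record.sensor_kind,
        sampling_rate=record.sampling_rate,
        frame_index=0,
        window=z,
    )
    return dft_magnitudes(frame)


def to_decibels(spec: SpectrumFeature, floor: float = DB_FLOOR) -> SpectrumFeature:
    """20 log10(max(|X[k]|, floor)) view of a linear-scale spectrum."""
    if spec.scale != "linear":
        raise ValueError("spectrum is already on a dB scale")
    if floor <= 0:
        raise ValueError("floor must be positive")
    db = 20.0 * np.log10(np.maximum(spec.magnitudes, floor))
    return dataclasses.replace(spec, magnitudes=db, scale="dB")


def spectral_peaks(spec: SpectrumFeature, min_relative_height: float = 1e-6) -> np.ndarray:
    """Frequencies of local maxima above 0 Hz, in ascending frequency order.

    Maxima below ``min_relative_height`` times the largest non-DC magnitude
    are ignored (numerical noise floor of an otherwise clean spectrum).
    """
    interior = spec.magnitudes[1:]
    peaks, _ = _sps.find_peaks(interior, height=min_relative_height * interior.max())
    return spec.frequencies[peaks + 1]


def _z_and_rate(signal, sampling_rate=None):
    if isinstance(signal, SignalRecord):
        return signal.samples_z, signal.sampling_rate
    if isinstance(signal, Frame):
        return signal.window, signal.sampling_rate
    if sampling_rate is None:
        raise ValueError("sampling_rate is required for a bare array")
    return np.asarray(signal, dtype=float), float(sampling_rate)


def estimate_fundamental(
    signal,
    search_band: tuple[float, float] = DEFAULT_F0_BAND,
    sampling_rate: float | None = None,
    voicing_threshold: float = 0.3,
) -> float:
    """Fundamental frequency by the autocorrelation maximum inside a band.

    The mean-removed signal's normalized autocorrelation is scanned over
    every lag whose equivalent frequency lies inside ``search_band``; the
    lag of the maximum is returned as Fs/lag.  Because every harmonic of a
    periodic signal contributes positively at the full-period lag, the scan
    prefers the true period over a strong harmonic's shorter one
    (octave robustness).  The biased estimator (fixed 1/N-style taper) is
    used so that, under noise, the shortest of equivalent period multiples
    wins.

    Raises
    ------
    ValueError
        Band outside (0, Fs/2).
    TooShortError
        Fewer than two periods of the band's low edge fit in the signal.
    NoPeriodicityError
        The best normalized autocorrelation falls below ``voicing_threshold``.
    """
    x, fs = _z_and_rate(signal, sampling_rate)
    f_lo, f_hi = search_band
    if not 0.0 < f_lo < f_hi < fs / 2.0:
        raise ValueError(f"search band {search_band} outside (0, Fs/2)")
    n = x.size
    required = math.ceil(2.0 * fs / f_lo)
    if n < required:
        raise TooShortError(n, required, what=f"autocorrelation down to {f_lo} Hz")

    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise NoPeriodicityError("signal is constant")
    lag_min = max(1, math.ceil(fs / f_hi))
    lag_max = min(n - 1, math.floor(fs / f_lo))
    lags = np.arange(lag_min, lag_max + 1)
    corr = np.array([np.dot(x[:-lag], x[lag:]) for lag in lags]) / denom
    best = int(np.argmax(corr))
    if corr[best] < voicing_threshold:
        raise NoPeriodicityError(
            f"max normalized autocorrelation {corr[best]:.3f} below "
            f"voicing threshold {voicing_threshold}"
        )
    return float(fs / lags[best])


def harmonic_features(
    spec: SpectrumFeature,
    fundamental: float,
    n_harmonics: int = 10,
    neighborhood: int = 1,
) -> HarmonicFeature:
    """Magnitudes at m*fundamental for m = 1..n_harmonics.

    Each harmonic's magnitude is the local maximum within ``neighborhood``
    bins of the nearest bin to m*fundamental, which absorbs spectral leakage
    when the harmonic does not fall exactly on a bin.
    """
    if spec.scale != "linear":
        raise ValueError("harmonic features require a linear-scale spectrum")
    if fundamental <= 0:
        raise ValueError("fundamental must be positive")
    nyquist = spec.frequencies[-1]
    df = spec.bin_width
    mags = np.empty(n_harmonics)
    for m in range(1, n_harmonics + 1):
        target = m * fundamental
        if target >= nyquist:
            raise ValueError(
                f"harmonic {m} at {target:.3f} Hz is at or above Nyquist "
                f"({nyquist:.3f} Hz)"
            )
        k = int(round(target / df))
        lo = max(1, k - neighborhood)
        hi = min(spec.magnitudes.size - 1, k + neighborhood)
        mags[m - 1] = spec.magnitudes[lo : hi + 1].max()
    return HarmonicFeature(
        subject_id=spec.subject_id,
        day=spec.day,
        trial=spec.trial,
        source_name=spec.source_name,
        frame_index=spec.frame_index,
        fundamental=float(fundamental),
        harmonic_mags=mags,
    )


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the non-provenance (feature) columns of a feature table."""
    return [c for c in table.columns if c not in PROVENANCE_COLUMNS]


def feature_matrix(
    records,
    window: int = FRAME_LENGTH,
    overlap: float = FRAME_OVERLAP,
    feature: str = "dft",
    f0_band: tuple[float, float] = DEFAULT_F0_BAND,
    n_harmonics: int = 10,
) -> pd.DataFrame:
    """Frame-level feature table for a list of records.

    One row per frame: the provenance columns of
    :data:`PROVENANCE_COLUMNS` followed by either the half-spectrum
    magnitudes (``feature="dft"``, columns ``m000``..) or the
    fundamental-plus-harmonics vector (``feature="harmonics"``, columns
    ``f0, h01..h10``).  For harmonic features the fundamental is estimated
    once per trial on the whole record.
    """
    if feature not in ("dft", "harmonics"):
        raise ValueError(f"unknown feature kind {feature!r}")
    rows = []
    vectors = []
    columns = None
    for record in records:
        if feature == "harmonics":
            f0 = estimate_fundamental(record, search_band=f0_band)
        for frame in frame_signal(record, window=window, overlap=overlap):
            spec = dft_magnitudes(frame)
            if feature == "dft":
                vec = spec.magnitudes
                if columns is None:
                    columns = [f"m{k:03d}" for k in range(vec.size)]
            else:
                vec = harmonic_features(spec, f0, n_harmonics=n_harmonics).as_vector()
                if columns is None:
                    columns = ["f0"] + [f"h{m:02d}" for m in range(1, n_harmonics + 1)]
            rows.append(
                (frame.subject_id, frame.day, frame.trial, frame.source_name,
                 frame.frame_index)
            )
            vectors.append(vec)
    if not rows:
        return pd.DataFrame(columns=list(PROVENANCE_COLUMNS))
    prov = pd.DataFrame(rows, columns=list(PROVENANCE_COLUMNS))
    feats = pd.DataFrame(np.vstack(vectors), columns=columns)
    return pd.concat([prov, feats], axis=1)


def concat_sources(tables) -> pd.DataFrame:
    """Concatenate feature vectors of several sources frame-by-frame.

    Tables are aligned on (subject_id, day, trial, frame_index); feature
    columns are suffixed with their source name.  Emulates using more than
    one marker simultaneously.
    """
    keys = ["subject_id", "day", "trial", "frame_index"]
    merged = None
    for table in tables:
        source = table["source"].iloc[0]
        fcols = feature_columns(table)
        part = table[keys + fcols].rename(
            columns={c: f"{c}_{source}" for c in fcols}
        )
        merged = part if merged is None else merged.merge(part, on=keys, how="inner")
    merged = merged.copy()
    merged["source"] = "+".join(t["source"].iloc[0] for t in tables)
    return merged[
        ["subject_id", "day", "trial", "source", "frame_index"]
        + [c for c in merged.columns if c not in keys + ["source"]]
    ]
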