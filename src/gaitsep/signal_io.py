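"""Session-file I/O and sliding-window segmentation of walking signals.

A *session file* holds one trial of one source (a motion-capture marker or
the thigh-worn accelerometer unit): a single JSON metadata comment line,
a ``time_s,x,y,z`` header, then one row per sample.  Trajectories are in
millimetres, accelerations in m/s^2.  Analysis consumes the vertical
(z) axis, segmented into fixed-length overlapping frames.
"""

from __future__ import annotations

import dataclasses
import glob as _glob
import json
from pathlib import Path

import numpy as np
import pandas as pd

SENSOR_KINDS = ("trajectory", "acceleration")
REQUIRED_COLUMNS = ("time_s", "x", "y", "z")

#: default frame length in samples and fractional overlap between frames
FRAME_LENGTH = 256
FRAME_OVERLAP = 0.75


class ParseError(ValueError):
    """A session file does not follow the expected dialect."""


class TooShortError(ValueError):
    """A signal is too short for the requested windowed operation."""

    def __init__(self, length: int, required: int, what: str = "sliding window"):
        self.length = int(length)
        self.required = int(required)
        super().__init__(
            f"signal has {length} samples but the {what} needs at least {required}"
        )


@dataclasses.dataclass
class SignalRecord:
    """One trial's three-axis time series with acquisition provenance.

    Units follow ``sensor_kind``: millimetres for marker trajectories,
    m/s^2 for accelerometer readings.
    """

    subject_id: int
    day: int
    trial: int
    source_name: str
    sensor_kind: str
    sampling_rate: float
    samples_x: np.ndarray
    samples_y: np.ndarray
    samples_z: np.ndarray

    def __post_init__(self) -> None:
        if self.sensor_kind not in SENSOR_KINDS:
            raise ValueError(f"unknown sensor_kind {self.sensor_kind!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.samples_x = np.asarray(self.samples_x, dtype=float)
        self.samples_y = np.asarray(self.samples_y, dtype=float)
        self.samples_z = np.asarray(self.samples_z, dtype=float)
        n = self.samples_z.size
        if n < 1:
            raise ValueError("record must contain at least one sample")
        if self.samples_x.size != n or self.samples_y.size != n:
            raise ValueError("axis lengths differ")

    @property
    def n_samples(self) -> int:
        return int(self.samples_z.size)

    @property
    def units(self) -> str:
        return "mm" if self.sensor_kind == "trajectory" else "m/s^2"

    def with_axes(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> "SignalRecord":
        """Copy of this record with replaced sample arrays (same provenance)."""
        return dataclasses.replace(self, samples_x=x, samples_y=y, samples_z=z)


@dataclasses.dataclass
class Frame:
    """A fixed-length window of one trial's z-axis signal.

    ``window`` is an owned copy: mutating one frame never alters the parent
    record or a sibling frame.
    """

    subject_id: int
    day: int
    trial: int
    source_name: str
    sensor_kind: str
    sampling_rate: float
    frame_index: int
    window: np.ndarray

    def __post_init__(self) -> None:
        self.window = np.array(self.window, dtype=float)  # copy -> value semantics
        if self.window.ndim != 1 or self.window.size < 2:
            raise ValueError("frame window must be a 1-D array of >= 2 samples")


def filename_for(record: SignalRecord) -> str:
    """Canonical session filename: subject<ID>_day<D>_trial<T>_<source>.csv."""
    return (
        f"subject{record.subject_id:02d}_day{record.day}"
        f"_trial{record.trial:02d}_{record.source_name}.csv"
    )


def write_session(record: SignalRecord, path) -> Path:
    """Write one record to ``path`` in the session CSV dialect."""
    path = Path(path)
    meta = {
        "subject_id": int(record.subject_id),
        "day": int(record.day),
        "trial": int(record.trial),
        "source_name": record.source_name,
        "sensor_kind": record.sensor_kind,
        "sampling_rate": float(record.sampling_rate),
    }
    t = np.arange(record.n_samples) / record.sampling_rate
    frame = pd.DataFrame(
        {"time_s": t, "x": record.samples_x, "y": record.samples_y, "z": record.samples_z}
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        # 12 significant digits keeps the write->read round trip below 1e-9
        frame.to_csv(fh, index=False, float_format="%.12g")
    return path


def read_session(path) -> SignalRecord:
    """Parse one session file; malformed content raises ParseError naming the line."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ParseError(f"{path}, line 1: missing '# {{...}}' metadata comment")
        try:
            meta = json.loads(first.lstrip("#").strip())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}, line 1: invalid metadata JSON ({exc})") from exc
        try:
            table = pd.read_csv(fh)
        except pd.errors.ParserError as exc:
            raise ParseError(f"{path}: malformed CSV body ({exc})") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    axes = {}
    for col in ("x", "y", "z"):
        values = pd.to_numeric(table[col], errors="coerce")
        bad = np.flatnonzero(values.isna().to_numpy())
        if bad.size:
            # +3: metadata line, header line, 1-based numbering
            raise ParseError(
                f"{path}, line {bad[0] + 3}: non-numeric value in column {col!r}"
            )
        axes[col] = values.to_numpy(dtype=float)

    needed = ("subject_id", "day", "trial", "source_name", "sensor_kind", "sampling_rate")
    lacking = [k for k in needed if k not in meta]
    if lacking:
        raise ParseError(f"{path}, line 1: metadata missing key(s) {lacking}")
    return SignalRecord(
        subject_id=int(meta["subject_id"]),
        day=int(meta["day"]),
        trial=int(meta["trial"]),
        source_name=str(meta["source_name"]),
        sensor_kind=str(meta["sensor_kind"]),
        sampling_rate=float(meta["sampling_rate"]),
        samples_x=axes["x"],
        samples_y=axes["y"],
        samples_z=axes["z"],
    )


def read_cohort(path_or_glob) -> list[SignalRecord]:
    """Load every session file in a directory (or matching a glob pattern)."""
    p = Path(path_or_glob)
    if p.is_dir():
        paths = sorted(p.glob("*.csv"))
    else:
        paths = [Path(s) for s in sorted(_glob.glob(str(path_or_glob)))]
    return [read_session(q) for q in paths]


def frame_signal(
    record: SignalRecord,
    window: int = FRAME_LENGTH,
    overlap: float = FRAME_OVERLAP,
) -> list[Frame]:
    """Segment a record's z-axis into overlapping fixed-length frames.

    The hop is ``window * (1 - overlap)`` samples and must be a positive
    integer (64 for the default 256/75%).  Trailing samples that do not fill
    a final window are discarded; frames never span trial boundaries because
    a record is a single trial.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if window < 2:
        raise ValueError("window must be at least 2 samples")
    step_f = window * (1.0 - overlap)
    step = int(round(step_f))
    if step <= 0 or abs(step_f - step) > 1e-9:
        raise ValueError(
            f"window*(1-overlap) = {step_f} is not a positive integer hop"
        )
    z = record.samples_z
    if z.size < window:
        raise TooShortError(z.size, window)
    n_frames = (z.size - window) // step + 1
    return [
        Frame(
            subject_id=record.subject_id,
            day=record.day,
            trial=record.trial,
            source_name=record.source_name,
            sensor_kind=record.sensor_kind,
            sampling_rate=record.sampling_rate,
            frame_index=k,
            window=z[k * step : k * step + window],
        )
        for k in range(n_frames)
    ]
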