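"""Butterworth filter bank and the pole-zero DC notch.

The ablation grid filters whole trials *before* framing (so frame edges are
not transient-contaminated) with causal single-pass filters: Butterworth
low-/high-/band-pass designs at the 3/6/10 Hz grid, and a first-order
band-stop at 0 Hz ("DC notch") built by pole-zero placement — a zero on the
unit circle at z = 1 and a pole at z = r just inside it,

    H(z) = (1 + r)/2 * (1 - z^-1) / (1 - r z^-1),

which is exactly zero at DC, unity at Nyquist, and for r close to 1 leaves
the ~1 Hz gait band essentially untouched.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as _sps

from .signal_io import Frame, SignalRecord

BUTTER_KINDS = ("lowpass", "highpass", "bandpass")


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Declarative description of one filter in the ablation grid."""

    kind: str
    sampling_rate: float
    cutoffs: tuple = ()
    order: int = 4
    pole_radius: float = 0.99

    def __post_init__(self) -> None:
        nyquist = self.sampling_rate / 2.0
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.kind == "dc_notch":
            if self.cutoffs:
                raise ValueError("dc_notch takes no cutoffs")
            if not 0.0 < self.pole_radius < 1.0:
                raise ValueError("pole_radius must lie in (0, 1) for stability")
        elif self.kind in BUTTER_KINDS:
            expected = 2 if self.kind == "bandpass" else 1
            if len(self.cutoffs) != expected:
                raise ValueError(f"{self.kind} needs {expected} cutoff(s)")
            if any(not 0.0 < c < nyquist for c in self.cutoffs):
                raise ValueError(
                    f"cutoffs {self.cutoffs} must lie strictly inside (0, "
                    f"{nyquist}) Hz"
                )
            if self.kind == "bandpass" and not self.cutoffs[0] < self.cutoffs[1]:
                raise ValueError("bandpass cutoffs must be ordered low < high")
            if self.order < 1:
                raise ValueError("order must be a positive integer")
        else:
            raise ValueError(f"unknown filter kind {self.kind!r}")


@dataclasses.dataclass
class DesignedFilter:
    """Transfer-function coefficients of a designed, stability-checked filter."""

    b: np.ndarray
    a: np.ndarray
    spec: FilterSpec

    def response(self, frequencies) -> np.ndarray:
        """Complex frequency response H(f) at the given frequencies (Hz)."""
        _, h = _sps.freqz(
            self.b, self.a, worN=np.atleast_1d(frequencies).astype(float),
            fs=self.spec.sampling_rate,
        )
        return h


def design_filter(spec: FilterSpec) -> DesignedFilter:
    """Design the filter described by ``spec`` and verify stability."""
    if spec.kind == "dc_notch":
        r = spec.pole_radius
        gain = (1.0 + r) / 2.0  # unity response at Nyquist
        b = gain * np.array([1.0, -1.0])
        a = np.array([1.0, -r])
    else:
        wn = spec.cutoffs[0] if len(spec.cutoffs) == 1 else list(spec.cutoffs)
        b, a = _sps.butter(spec.order, wn, btype=spec.kind, fs=spec.sampling_rate)
    poles = np.roots(a)
    if poles.size and np.max(np.abs(poles)) >= 1.0:
        raise RuntimeError(f"designed filter is unstable: {spec}")
    return DesignedFilter(b=np.asarray(b), a=np.asarray(a), spec=spec)


def _lfilter(filt: DesignedFilter, x: np.ndarray) -> np.ndarray:
    # steady-state initial conditions at the first sample's level suppress
    # the startup step transient (trials begin mid-walk at a large DC offset)
    zi = _sps.lfilter_zi(filt.b, filt.a) * x[0]
    y, _ = _sps.lfilter(filt.b, filt.a, x, zi=zi)
    return y


def apply_filter(target, filt, sampling_rate: float | None = None):
    """Causal single-pass filtering; output has the input's length and type.

    ``target`` may be a SignalRecord (all three axes filtered), a Frame
    (its window filtered) or a bare 1-D array with ``sampling_rate`` given.
    The filter's design rate must match the signal's.
    """
    if isinstance(filt, FilterSpec):
        filt = design_filter(filt)

    def check_rate(rate: float) -> None:
        if abs(rate - filt.spec.sampling_rate) > 1e-9:
            raise ValueError(
                f"sampling-rate mismatch: signal at {rate} Hz, filter designed "
                f"for {filt.spec.sampling_rate} Hz"
            )

    if isinstance(target, SignalRecord):
        check_rate(target.sampling_rate)
        return target.with_axes(
            _lfilter(filt, target.samples_x),
            _lfilter(filt, target.samples_y),
            _lfilter(filt, target.samples_z),
        )
    if isinstance(target, Frame):
        check_rate(target.sampling_rate)
        return dataclasses.replace(target, window=_lfilter(filt, target.window))
    if sampling_rate is not None:
        check_rate(sampling_rate)
    x = np.asarray(target, dtype=float)
    return _lfilter(filt, x)


def filter_bank(sampling_rate: float) -> dict[str, tuple[FilterSpec, ...]]:
    """The ablation grid as named filter chains.

    Every Butterworth variant is composed with the DC notch (the ablations
    compare band content with the DC bias already removed); ``raw`` is the
    unfiltered signal and ``notch`` removes DC only.
    """
    notch = FilterSpec("dc_notch", sampling_rate)

    def lp(f):
        return FilterSpec("lowpass", sampling_rate, (f,))

    def hp(f):
        return FilterSpec("highpass", sampling_rate, (f,))

    return {
        "raw": (),
        "notch": (notch,),
        "lp3": (notch, lp(3.0)),
        "lp6": (notch, lp(6.0)),
        "lp10": (notch, lp(10.0)),
        "hp3": (notch, hp(3.0)),
        "hp6": (notch, hp(6.0)),
        "hp10": (notch, hp(10.0)),
        "bp6_10": (notch, FilterSpec("bandpass", sampling_rate, (6.0, 10.0))),
    }


def apply_variant(record: SignalRecord, variant) -> SignalRecord:
    """Apply a named filter-bank variant (or an explicit chain) to a record."""
    if isinstance(variant, str):
        bank = filter_bank(record.sampling_rate)
        if variant not in bank:
            raise ValueError(
                f"unknown filter variant {variant!r}; known: {sorted(bank)}"
            )
        chain = bank[variant]
    else:
        chain = tuple(variant)
    for spec in chain:
        record = apply_filter(record, spec)
    return record
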