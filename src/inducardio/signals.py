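"""Core signal container and ARMA low-pass machinery.

The raw sensor stream is a uniformly sampled series of inductance-derived
counts.  Respiration is the dominant, slow (< 1 Hz) component; it is
extracted with a low-pass Butterworth filter applied causally through its
ARMA difference equation

    y[n] = sum_k b[k] * x[n-k] + sum_j (-a[j]) * y[n-j],

whose recursive part introduces a group delay that downstream stages
measure and compensate rather than avoiding it with zero-phase filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

__all__ = [
    "Signal",
    "FilterCoefficients",
    "remove_offset",
    "design_lowpass",
    "apply_filter",
    "normalize",
]

#: Units a Signal may carry.  "counts" is the raw 16-bit converter output,
#: "adimensional" the normalized trace, "meter" a chest-displacement series
#: driving the sensor model, "henry" a coil-inductance series.
UNITS = frozenset({"counts", "adimensional", "millivolt", "henry", "meter"})


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued series.

    Parameters
    ----------
    samples:
        The sample values; coerced to a float64 array.  Must be finite and
        non-empty.
    fs:
        Sampling rate in Hz, strictly positive.
    unit:
        One of ``counts``, ``adimensional``, ``millivolt``, ``henry``,
        ``meter``.
    """

    samples: np.ndarray
    fs: float
    unit: str = "adimensional"

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=np.float64)
        if x.ndim != 1:
            raise ValueError("Signal samples must be one-dimensional")
        if x.size < 1:
            raise ValueError("Signal must contain at least one sample")
        if not np.all(np.isfinite(x)):
            raise ValueError("Signal samples must all be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {sorted(UNITS)}")
        object.__setattr__(self, "samples", x)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Record length in seconds (N / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample instants in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, unit: str | None = None) -> "Signal":
        """A copy of this signal with new samples (and optionally a new unit)."""
        return Signal(samples, self.fs, self.unit if unit is None else unit)


@dataclass(frozen=True)
class FilterCoefficients:
    """ARMA (IIR) filter coefficients in transfer-function form.

    ``b`` are the feed-forward (MA) coefficients, ``a`` the recursive (AR)
    coefficients with ``a[0] = 1``.  For a low-pass design the DC gain
    ``sum(b)/sum(a)`` is unity to within 1e-6.
    """

    b: np.ndarray
    a: np.ndarray
    order: int
    cutoff_hz: float
    fs_hz: float
    is_lowpass: bool = field(default=True)

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=np.float64)
        a = np.asarray(self.a, dtype=np.float64)
        if b.size < 1 or a.size < 1:
            raise ValueError("coefficient arrays must be non-empty")
        if abs(a[0] - 1.0) > 1e-12:
            raise ValueError("recursive coefficients must be normalized to a[0] = 1")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.is_lowpass:
            dc = b.sum() / a.sum()
            if abs(dc - 1.0) > 1e-6:
                raise ValueError(f"low-pass DC gain is {dc}, expected 1 within 1e-6")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "a", a)

    def magnitude(self, freqs_hz) -> np.ndarray:
        """|H(f)| evaluated at the given frequencies in Hz."""
        _, h = scipy.signal.freqz(self.b, self.a, worN=np.atleast_1d(freqs_hz), fs=self.fs_hz)
        return np.abs(h)

    def group_delay_samples(self, freq_hz: float) -> float:
        """Group delay of the filter at one frequency, in samples."""
        _, gd = scipy.signal.group_delay((self.b, self.a), w=np.array([freq_hz]), fs=self.fs_hz)
        return float(gd[0])


def remove_offset(s: Signal) -> Signal:
    """Subtract the mean so the series is zero-mean (idempotent)."""
    return s.with_samples(s.samples - s.samples.mean())


def design_lowpass(order: int, cutoff_hz: float, fs_hz: float) -> FilterCoefficients:
    """Design a digital Butterworth low-pass filter.

    The default pipeline uses order 7 with a 1 Hz cutoff at fs = 20 Hz to
    isolate respiration (0.2–0.33 Hz) from the cardiac component
    (0.67–3.3 Hz).  The half-power (−3 dB) point of the design sits at
    ``cutoff_hz`` by the Butterworth definition.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if not (0 < cutoff_hz < fs_hz / 2):
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie strictly between 0 and Nyquist ({fs_hz / 2} Hz)"
        )
    b, a = scipy.signal.butter(order, cutoff_hz, btype="low", fs=fs_hz)
    return FilterCoefficients(b=b, a=a, order=order, cutoff_hz=cutoff_hz, fs_hz=fs_hz)


def apply_filter(c: FilterCoefficients, s: Signal, initial: str = "zero") -> Signal:
    """Run the ARMA difference equation causally.

    Uses the direct-form transposed-II realization; length is preserved
    and the recursive part introduces a frequency-dependent group delay
    that is estimated and removed downstream by the alignment stage.

    ``initial`` selects the filter state at n = 0: ``"zero"`` (the plain
    difference equation with zero initial conditions) or ``"steady"``
    (state matching a constant input equal to the first sample, which
    suppresses the step-response transient when filtering a short
    analysis window that starts mid-breath).
    """
    if initial == "zero":
        y = scipy.signal.lfilter(c.b, c.a, s.samples)
    elif initial == "steady":
        zi = scipy.signal.lfilter_zi(c.b, c.a) * s.samples[0]
        y, _ = scipy.signal.lfilter(c.b, c.a, s.samples, zi=zi)
    else:
        raise ValueError(f"initial must be 'zero' or 'steady', got {initial!r}")
    return s.with_samples(y)


def normalize(s: Signal) -> Signal:
    """Remove the mean and scale to a maximum absolute value of 1.

    The result carries the ``adimensional`` unit.  Raises on an all-zero
    (or constant) input, whose scale is undefined.
    """
    x = s.samples - s.samples.mean()
    peak = np.abs(x).max()
    if peak == 0.0:
        raise ValueError("cannot normalize a constant (or all-zero) signal")
    return Signal(x / peak, s.fs, "adimensional")
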