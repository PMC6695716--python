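"""Planar spiral coil model and inductance-to-counts conversion.

A flat spiral coil woven into fabric over the cardiac apex forms the
sensing element of an LC resonator read out by an inductance-to-digital
converter.  Body tissue is predominantly water and hence weakly
diamagnetic, so bringing the chest wall closer to the coil *lowers* the
measured inductance; chest-wall displacement from respiration and the
apex beat therefore modulates L(t), which the converter digitizes.

The coil inductance follows the current-sheet approximation

    L = K1 * mu0 * N^2 * D_avg / (1 + K2 * phi)

with layout coefficients (K1, K2) per winding geometry, N turns, average
diameter D_avg and fill factor phi = (D_out - D_in)/(D_out + D_in).
All computation is in SI units (henries, meters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import Signal

__all__ = [
    "CoilSpec",
    "LAYOUT_COEFFICIENTS",
    "MU_0",
    "spiral_inductance",
    "modulate_inductance",
    "quantize_counts",
    "dequantize_counts",
]

MU_0 = 4e-7 * np.pi  # vacuum permeability, H/m

#: Current-sheet layout coefficients (K1, K2) for standard spiral layouts.
LAYOUT_COEFFICIENTS: dict[str, tuple[float, float]] = {
    "square": (2.34, 2.75),
    "hexagonal": (2.33, 3.82),
    "octagonal": (2.25, 3.55),
    "circular": (2.25, 3.55),
}

FULL_SCALE_COUNTS = 65535  # 16-bit converter output


@dataclass(frozen=True)
class CoilSpec:
    """Geometry of a planar spiral coil.

    ``d_avg`` is in meters; ``k1``/``k2`` default to the current-sheet
    coefficients for the chosen ``layout`` but may be overridden.
    """

    n_turns: int
    d_avg: float
    fill_factor: float
    layout: str = "square"
    k1: float | None = None
    k2: float | None = None

    def __post_init__(self) -> None:
        if self.n_turns < 0:
            raise ValueError("n_turns must be >= 0")
        if not (0 <= self.fill_factor < 1):
            raise ValueError("fill_factor must lie in [0, 1)")
        if self.layout not in LAYOUT_COEFFICIENTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        k1_default, k2_default = LAYOUT_COEFFICIENTS[self.layout]
        k1 = k1_default if self.k1 is None else self.k1
        k2 = k2_default if self.k2 is None else self.k2
        if k1 <= 0 or k2 <= 0:
            raise ValueError("layout coefficients must be positive")
        object.__setattr__(self, "k1", float(k1))
        object.__setattr__(self, "k2", float(k2))


def spiral_inductance(c: CoilSpec) -> float:
    """Inductance of a planar spiral coil in henries (current-sheet formula)."""
    return c.k1 * MU_0 * c.n_turns**2 * c.d_avg / (1.0 + c.k2 * c.fill_factor)


def modulate_inductance(baseline: float, displacement: Signal, sensitivity: float) -> Signal:
    """First-order displacement-to-inductance model.

    ``L(t) = baseline - sensitivity * displacement(t)``: positive
    displacement means the (diamagnetic) chest wall approaches the coil,
    so inductance drops.  Raises if the modulation drives L to zero or
    below, which would be unphysical.
    """
    if baseline <= 0:
        raise ValueError("baseline inductance must be positive")
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    if displacement.unit != "meter":
        raise ValueError(f"displacement must be in meters, got unit {displacement.unit!r}")
    l = baseline - sensitivity * displacement.samples
    if np.any(l <= 0):
        raise ValueError("modulation drives inductance to a non-positive value")
    return Signal(l, displacement.fs, "henry")


def quantize_counts(l: Signal, full_scale: tuple[float, float]) -> Signal:
    """Map an inductance series onto 16-bit converter counts.

    ``full_scale = (Lmin, Lmax)`` maps affinely onto [0, 65535] with
    round-half-even; the map is monotone.  Samples outside full scale are
    a converter overrange and raise.
    """
    lmin, lmax = full_scale
    if not lmin < lmax:
        raise ValueError("full scale must satisfy Lmin < Lmax")
    x = l.samples
    if np.any(x < lmin) or np.any(x > lmax):
        raise ValueError("inductance sample outside converter full scale")
    counts = np.rint((x - lmin) / (lmax - lmin) * FULL_SCALE_COUNTS)
    return Signal(counts, l.fs, "counts")


def dequantize_counts(counts: Signal, full_scale: tuple[float, float]) -> Signal:
    """Inverse of :func:`quantize_counts` up to half an LSB."""
    lmin, lmax = full_scale
    if not lmin < lmax:
        raise ValueError("full scale must satisfy Lmin < Lmax")
    l = lmin + counts.samples / FULL_SCALE_COUNTS * (lmax - lmin)
    return Signal(l, counts.fs, "henry")
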