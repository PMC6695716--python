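"""Synthetic cardiorespiratory signals standing in for the hardware.

The inductive stream is modelled as chest-wall displacement

    s(t) = sB(t) + sH(t) + u(t)

where sB is respiration (quasi-periodic, 3–5 s period, a few millimetres
of chest excursion), sH the mechanical apex impulse (a narrow unimodal
bump per beat, a fraction of a millimetre), and u uniform measurement
noise whose level encodes whether the coil is pressed against the chest.
The displacement drives the spiral-coil model and is digitized to 16-bit
counts, so generated streams exercise the full processing chain.

A companion ECG generator produces a P–QRS–T template train with known
R-peak positions, used as ground truth for the QRS detector and for
agreement studies between the two sensing chains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .sensor import FULL_SCALE_COUNTS, modulate_inductance, quantize_counts
from .signals import Signal

__all__ = [
    "InductiveScenario",
    "SyntheticEcg",
    "gen_respiration",
    "gen_cardiac",
    "gen_inductive",
    "gen_ecg",
    "cardiac_beat_times",
]

# Displacement-to-counts chain defaults (SI).  10 nH/mm sensitivity about a
# 3.3 uH baseline with a +/-100 nH converter full scale: one LSB is ~3 pH,
# i.e. ~0.3 um of displacement, far below the cardiac bump.
BASELINE_H = 3.3e-6
SENSITIVITY_H_PER_M = 1e-5
FULL_SCALE_H = (BASELINE_H - 1e-7, BASELINE_H + 1e-7)

# Noise calibration: amplitude ratio cardiac/noise when the coil is pressed
# against the chest versus worn loose.
PRESSED_CARDIAC_TO_NOISE = 5.0
UNPRESSED_CARDIAC_TO_NOISE = 0.8

_BREATH_SKEW = 0.3  # phase-warp depth: inhale/exhale asymmetry of the breath cycle


@dataclass(frozen=True)
class InductiveScenario:
    """Parameters of one simulated inductive recording.

    Amplitudes are chest-wall displacements in meters.  ``noise_amp=None``
    selects the pressed/unpressed default calibration; ``breath_hold`` is
    an optional ``(t_start, t_end)`` interval in seconds during which
    respiration is suspended.
    """

    duration_s: float = 30.0
    fs: float = 20.0
    hr_bpm: float = 72.0
    resp_period_s: float = 4.0
    resp_amp: float = 2e-3
    cardiac_amp: float = 2.5e-4
    cardiac_width_s: float = 0.045
    noise_amp: float | None = None
    pressed: bool = True
    breath_hold: tuple[float, float] | None = None
    resp_jitter: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not (40 <= self.hr_bpm <= 200):
            raise ValueError("hr_bpm must lie in [40, 200]")
        if not (3 <= self.resp_period_s <= 5):
            raise ValueError("resp_period_s must lie in [3, 5]")
        if not (self.resp_amp > self.cardiac_amp > 0):
            raise ValueError("require resp_amp > cardiac_amp > 0")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if self.breath_hold is not None:
            t0, t1 = self.breath_hold
            if not (0 <= t0 < t1 <= self.duration_s):
                raise ValueError("breath_hold must be an interval within [0, duration]")

    @property
    def effective_noise_amp(self) -> float:
        """Noise amplitude, defaulting to the pressed/unpressed calibration."""
        if self.noise_amp is not None:
            return self.noise_amp
        ratio = PRESSED_CARDIAC_TO_NOISE if self.pressed else UNPRESSED_CARDIAC_TO_NOISE
        return self.cardiac_amp / ratio

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _rng(sc: InductiveScenario, stream: int) -> np.random.Generator:
    # Independent substreams per component so e.g. the noise draw does not
    # change the breath-cycle jitter.
    return np.random.default_rng([sc.seed, stream])


def _breath_shape(phase: np.ndarray) -> np.ndarray:
    """Skewed-cosine breath cycle on fractional phase, range [-0.5, 0.5].

    A raised cosine whose phase is warped so inhalation is faster than
    exhalation — quiet-breathing chest excursion is near-sinusoidal with
    mild asymmetry.  Being infinitely smooth, its harmonics decay fast,
    matching the smooth quasi-sinusoidal character of real chest motion.
    """
    p = np.mod(phase, 1.0)
    warped = p + _BREATH_SKEW * np.sin(2.0 * np.pi * p) / (2.0 * np.pi)
    return -0.5 * np.cos(2.0 * np.pi * warped)


def gen_respiration(sc: InductiveScenario) -> Signal:
    """Respiration displacement sB: quasi-periodic with per-cycle jitter.

    Cycle lengths are drawn as ``resp_period_s * (1 + resp_jitter * U)``
    with U uniform on [-1, 1].  Inside a breath-hold interval the output
    is identically zero, with cosine on/off ramps of at most 1 s just
    outside the interval.
    """
    rng = _rng(sc, 1)
    t = np.arange(sc.n_samples) / sc.fs
    # Cumulative cycle boundaries, then fractional phase by interpolation.
    boundaries = [0.0]
    while boundaries[-1] < sc.duration_s:
        period = sc.resp_period_s * (1.0 + sc.resp_jitter * rng.uniform(-1.0, 1.0))
        boundaries.append(boundaries[-1] + period)
    boundaries = np.asarray(boundaries)
    phase = np.interp(t, boundaries, np.arange(boundaries.size, dtype=float))
    x = sc.resp_amp * 2.0 * _breath_shape(phase)

    if sc.breath_hold is not None:
        t0, t1 = sc.breath_hold
        ramp = 1.0  # seconds
        env = np.ones_like(t)
        inside = (t >= t0) & (t <= t1)
        env[inside] = 0.0
        pre = (t >= t0 - ramp) & (t < t0)
        env[pre] = 0.5 * (1.0 + np.cos(np.pi * (t[pre] - (t0 - ramp)) / ramp))
        post = (t > t1) & (t <= t1 + ramp)
        env[post] = 0.5 * (1.0 - np.cos(np.pi * (t[post] - t1) / ramp))
        x = x * env
    return Signal(x, sc.fs, "meter")


def cardiac_beat_times(sc: InductiveScenario) -> np.ndarray:
    """Beat instants in seconds: a regular train at hr_bpm from t = 0."""
    period = 60.0 / sc.hr_bpm
    return np.arange(0.0, sc.duration_s, period)


def gen_cardiac(sc: InductiveScenario) -> Signal:
    """Mechanical apex impulse train sH: one Gaussian bump per beat.

    The bump's effective width (6 sigma) must be narrower than the beat
    period, otherwise consecutive pulses merge and the scenario is
    rejected.
    """
    period = 60.0 / sc.hr_bpm
    if 6.0 * sc.cardiac_width_s >= period:
        raise ValueError(
            f"cardiac pulse width {6 * sc.cardiac_width_s:.3f} s must be "
            f"narrower than the beat period {period:.3f} s"
        )
    t = np.arange(sc.n_samples) / sc.fs
    x = np.zeros_like(t)
    for tc in cardiac_beat_times(sc):
        x += np.exp(-0.5 * ((t - tc) / sc.cardiac_width_s) ** 2)
    return Signal(sc.cardiac_amp * x, sc.fs, "meter")


def gen_inductive(sc: InductiveScenario, return_components: bool = False):
    """Full synthetic inductive stream in 16-bit counts.

    Composes respiration + cardiac + uniform noise in displacement,
    passes the sum through the coil modulation model and quantizes to
    counts.  With ``return_components=True`` also returns a dict with the
    ``respiration``, ``cardiac`` and ``noise`` displacement signals for
    ground-truth checks.
    """
    sb = gen_respiration(sc)
    sh = gen_cardiac(sc)
    noise_amp = sc.effective_noise_amp
    rng = _rng(sc, 3)
    u = rng.uniform(-noise_amp, noise_amp, size=sc.n_samples) if noise_amp > 0 else np.zeros(sc.n_samples)
    disp = Signal(sb.samples + sh.samples + u, sc.fs, "meter")
    counts = quantize_counts(modulate_inductance(BASELINE_H, disp, SENSITIVITY_H_PER_M), FULL_SCALE_H)
    if return_components:
        return counts, {
            "respiration": sb,
            "cardiac": sh,
            "noise": Signal(u, sc.fs, "meter"),
            "displacement": disp,
        }
    return counts


def counts_lsb_displacement() -> float:
    """Displacement equivalent of one converter LSB, in meters."""
    lmin, lmax = FULL_SCALE_H
    return (lmax - lmin) / FULL_SCALE_COUNTS / SENSITIVITY_H_PER_M


class SyntheticEcg(NamedTuple):
    signal: Signal
    r_peaks: np.ndarray  # ground-truth R sample indices


def gen_ecg(
    duration_s: float = 30.0,
    fs: float = 200.0,
    hr_bpm: float = 60.0,
    qrs_width_ms: float = 80.0,
    p_amp: float = 0.15,
    t_amp: float = 0.3,
    r_amp: float = 1.0,
    noise_amp: float = 0.02,
    wander_amp: float = 0.0,
    wander_freq_hz: float = 0.3,
    seed: int = 0,
) -> SyntheticEcg:
    """Single-lead ECG as a repeated P-QRS-T Gaussian template (in mV).

    Beats form a regular train; the template's P/T offsets shrink
    proportionally when the beat period drops below 0.8 s so waves never
    overlap at high rates.  Optional baseline wander is a sub-0.5 Hz
    sinusoid; noise is additive uniform.  Returns the signal together with
    the ground-truth R-peak sample indices.
    """
    if not (40 <= hr_bpm <= 200):
        raise ValueError("hr_bpm must lie in [40, 200]")
    if not (0 < qrs_width_ms < 200):
        raise ValueError("qrs_width_ms must lie in (0, 200)")
    if wander_freq_hz >= 0.5:
        raise ValueError("baseline wander must stay below 0.5 Hz")
    period = 60.0 / hr_bpm
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # Template geometry (seconds), compressed at short beat periods.
    squeeze = min(1.0, period / 0.8)
    sigma_r = qrs_width_ms / 1000.0 / 6.0
    waves = [
        (-0.2 * squeeze, 0.025, p_amp),          # P
        (-2.0 * sigma_r, sigma_r * 0.7, -0.15 * r_amp),  # Q
        (0.0, sigma_r, r_amp),                   # R
        (2.0 * sigma_r, sigma_r * 0.7, -0.2 * r_amp),    # S
        (0.3 * squeeze, 0.06 * squeeze, t_amp),  # T
    ]

    start = 0.3 * squeeze  # leave room for the first P wave
    beat_times = np.arange(start, duration_s - 0.05, period)
    x = np.zeros(n)
    for tc in beat_times:
        for off, sigma, amp in waves:
            x += amp * np.exp(-0.5 * ((t - (tc + off)) / sigma) ** 2)

    if wander_amp:
        x += wander_amp * np.sin(2 * np.pi * wander_freq_hz * t)
    if noise_amp:
        rng = np.random.default_rng([seed, 7])
        x += rng.uniform(-noise_amp, noise_amp, size=n)

    r_peaks = np.rint(beat_times * fs).astype(int)
    return SyntheticEcg(Signal(x, fs, "millivolt"), r_peaks)


def with_seed(sc: InductiveScenario, seed: int) -> InductiveScenario:
    """Convenience: the same scenario with a different seed."""
    return replace(sc, seed=seed)
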