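"""Windowed heart-rate and respiration-rate estimation.

The period of the cardiac difference signal d is read off its raw
autocorrelation

    CXX[k] = sum_{n=0}^{N-k} d[n] * d[n+k],

restricted to physiological lags: T in [Tmin, Tmax] with
Tmin = round(60/bpm_max * fs) and Tmax = round(60/bpm_min * fs)
(6 and 30 samples at fs = 20 Hz for the 40–200 bpm band).  The rate is
bpm = 60/T * fs.  The same machinery with a 6–30 breaths/min band gives
a respiration rate from the low-pass output.

`estimate_heart_rate` orchestrates the full chain per sliding analysis
window: offset removal, low-pass filtering, delay alignment, difference,
autocorrelation, period pick.  Windows with no admissible peak are
flagged invalid rather than raising, so a whole recording always yields
a report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .separation import estimate_delay
from .signals import Signal, apply_filter, design_lowpass, remove_offset

__all__ = [
    "HeartRateEstimate",
    "RespirationEstimate",
    "autocorrelation",
    "lag_bounds",
    "estimate_period",
    "bpm_from_period",
    "estimate_heart_rate",
    "estimate_respiration_rate",
    "windowed_report",
]


def autocorrelation(d: Signal, max_lag: int) -> np.ndarray:
    """Raw autocorrelation for lags 0..max_lag (CXX[0] is the energy)."""
    x = d.samples
    n = x.size
    if n < 1:
        raise ValueError("empty signal")
    if not (0 < max_lag < n):
        raise ValueError(f"max_lag must lie in (0, N), got {max_lag} for N = {n}")
    return np.array([np.dot(x[: n - k], x[k:]) for k in range(max_lag + 1)])


def lag_bounds(fs: float, bpm_min: float = 40.0, bpm_max: float = 200.0) -> tuple[int, int]:
    """Admissible period range in samples for a rate band in 1/min.

    Tmin = round(60/bpm_max * fs), Tmax = round(60/bpm_min * fs); e.g.
    (6, 30) samples at fs = 20 Hz for 40–200 bpm.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not (0 < bpm_min < bpm_max):
        raise ValueError("need 0 < bpm_min < bpm_max")
    tmin = int(np.rint(60.0 / bpm_max * fs))
    tmax = int(np.rint(60.0 / bpm_min * fs))
    if tmin < 1 or tmin >= tmax:
        raise ValueError(f"lag bounds collapsed: Tmin={tmin}, Tmax={tmax}")
    return tmin, tmax


def estimate_period(cxx: np.ndarray, tmin: int, tmax: int) -> int | None:
    """Lag of the highest local autocorrelation maximum within [tmin, tmax].

    A local maximum requires CXX[k] > CXX[k-1] and CXX[k] >= CXX[k+1]; of
    equal-height peaks the smallest lag wins.  Returns None when no local
    maximum lies in range (the caller flags the window invalid).
    """
    if tmin < 1 or tmin >= tmax:
        raise ValueError("need 1 <= tmin < tmax")
    if tmax + 1 >= cxx.size:
        raise ValueError("autocorrelation too short: need max_lag > tmax")
    best_lag, best_val = None, -np.inf
    for k in range(tmin, tmax + 1):
        if cxx[k] > cxx[k - 1] and cxx[k] >= cxx[k + 1] and cxx[k] > best_val:
            best_lag, best_val = k, cxx[k]
    return best_lag


def bpm_from_period(t: int, fs: float) -> float:
    """Convert a period in samples to a rate: bpm = 60/T * fs."""
    if t < 1:
        raise ValueError("period must be at least one sample")
    return 60.0 / t * fs


@dataclass(frozen=True)
class HeartRateEstimate:
    """One analysis window's result; ``bpm`` is None when invalid."""

    period_samples: int | None
    bpm: float | None
    window: tuple[float, float]
    valid: bool
    method_note: str = ""


@dataclass(frozen=True)
class RespirationEstimate:
    period_samples: int | None
    rpm: float | None
    valid: bool
    method_note: str = ""


def _window_slices(n: int, fs: float, window_s: float, hop_s: float):
    wlen = int(round(window_s * fs))
    hop = max(1, int(round(hop_s * fs)))
    start = 0
    while start + wlen <= n:
        yield start, start + wlen
        start += hop


def estimate_heart_rate(
    s: Signal,
    window_s: float = 15.0,
    hop_s: float = 5.0,
    order: int = 7,
    cutoff_hz: float = 1.0,
    bpm_min: float = 40.0,
    bpm_max: float = 200.0,
    max_lag_s: float = 2.0,
) -> list[HeartRateEstimate]:
    """Run the full five-step chain on sliding analysis windows.

    Per window: remove the offset, extract respiration with the low-pass
    ARMA filter, align and subtract it (delay from correlation/AMDF),
    then locate the cardiac period in the autocorrelation of the
    difference within the bpm-derived lag bounds.
    """
    tmin, tmax = lag_bounds(s.fs, bpm_min, bpm_max)
    wlen = int(round(window_s * s.fs))
    if wlen < 2 * tmax:
        raise ValueError(
            f"window of {wlen} samples is too short: need at least 2*Tmax = {2 * tmax}"
        )
    if wlen > len(s):
        raise ValueError("window is longer than the recording")
    coeffs = design_lowpass(order, cutoff_hz, s.fs)
    max_lag = min(int(round(max_lag_s * s.fs)), wlen - 2)

    estimates: list[HeartRateEstimate] = []
    for i0, i1 in _window_slices(len(s), s.fs, window_s, hop_s):
        win = Signal(s.samples[i0:i1], s.fs, s.unit)
        sn = remove_offset(win)
        sstar = apply_filter(coeffs, sn, initial="steady")
        align = estimate_delay(sn, sstar, max_lag)
        d = align.d
        window_bounds = (i0 / s.fs, i1 / s.fs)
        if len(d) <= tmax + 1:
            estimates.append(
                HeartRateEstimate(None, None, window_bounds, False, "difference too short")
            )
            continue
        cxx = autocorrelation(d, tmax + 1)
        t = estimate_period(cxx, tmin, tmax)
        if t is None:
            estimates.append(
                HeartRateEstimate(None, None, window_bounds, False, "no autocorrelation peak in band")
            )
        else:
            estimates.append(
                HeartRateEstimate(
                    t,
                    bpm_from_period(t, s.fs),
                    window_bounds,
                    True,
                    f"offset={align.chosen_offset}",
                )
            )
    return estimates


def estimate_respiration_rate(
    sstar: Signal,
    rpm_min: float = 6.0,
    rpm_max: float = 30.0,
) -> RespirationEstimate:
    """Respiration rate (breaths/min) from the low-pass output.

    Same autocorrelation peak pick with lag bounds from the 6–30
    breaths/min band.  If the dominant periodicity sits below Tmin (i.e.
    faster than any plausible breath — typically residual cardiac
    content), the estimate is flagged out-of-band rather than reported.
    """
    tmin, tmax = lag_bounds(sstar.fs, rpm_min, rpm_max)
    x = remove_offset(sstar)
    if len(x) <= tmax + 1:
        return RespirationEstimate(None, None, False, "signal shorter than the slowest breath")
    cxx = autocorrelation(x, tmax + 1)
    t = estimate_period(cxx, tmin, tmax)
    if t is None:
        return RespirationEstimate(None, None, False, "no autocorrelation peak in band")
    # Out-of-band guard: when most of the energy sits above the breathing
    # band (residual cardiac content), an in-band comb peak is spurious.
    spectrum = np.abs(np.fft.rfft(x.samples)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1.0 / sstar.fs)
    band_hz = rpm_max / 60.0
    total = spectrum[1:].sum()
    in_band = spectrum[(freqs > 0) & (freqs <= band_hz)].sum()
    if total > 0 and in_band < 0.5 * total:
        return RespirationEstimate(None, None, False, "dominant content out of band")
    # Guard against windows with essentially no breathing (breath hold):
    # the in-band peak must carry a meaningful share of the energy.
    if cxx[0] <= 0 or cxx[t] < 0.1 * cxx[0]:
        return RespirationEstimate(None, None, False, "in-band peak below energy floor")
    return RespirationEstimate(t, bpm_from_period(t, sstar.fs), True, "")


def windowed_report(
    s: Signal,
    window_s: float = 15.0,
    hop_s: float = 5.0,
    order: int = 7,
    cutoff_hz: float = 1.0,
    bpm_min: float = 40.0,
    bpm_max: float = 200.0,
) -> pd.DataFrame:
    """Per-window heart-rate and respiration-rate report.

    Columns: window_start_s, window_end_s, bpm, valid, resp_rate (NaN
    where the respective estimate is invalid).
    """
    estimates = estimate_heart_rate(
        s, window_s, hop_s, order=order, cutoff_hz=cutoff_hz, bpm_min=bpm_min, bpm_max=bpm_max
    )
    coeffs = design_lowpass(order, cutoff_hz, s.fs)
    rows = []
    for est in estimates:
        i0 = int(round(est.window[0] * s.fs))
        i1 = int(round(est.window[1] * s.fs))
        win = remove_offset(Signal(s.samples[i0:i1], s.fs, s.unit))
        sstar = apply_filter(coeffs, win, initial="steady")
        resp = estimate_respiration_rate(sstar)
        rows.append(
            {
                "window_start_s": est.window[0],
                "window_end_s": est.window[1],
                "bpm": est.bpm if est.valid else np.nan,
                "valid": est.valid,
                "resp_rate": resp.rpm if resp.valid else np.nan,
            }
        )
    return pd.DataFrame(rows)
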