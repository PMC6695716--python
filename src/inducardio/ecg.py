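"""Reference single-lead ECG chain: conditioning, baseline, QRS detection.

The ECG channel validates the inductive heart-rate estimates.  Software
conditioning mirrors the acquisition amplifier settings (1 Hz high-pass
to stabilize the baseline, 35 Hz low-pass, 50 Hz mains notch).  Baseline
wander is estimated with a two-scale median filter and subtracted so the
detector sees a flat isoelectric line.  Beats are found with a
derivative–energy detector (derivative, squaring, moving-window
integration) followed by correction rules: an adaptive amplitude
threshold, a 200 ms refractory period that rejects tall T waves, and a
search-back pass when an RR gap exceeds 1.66x the running median RR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .signals import Signal

__all__ = [
    "QrsResult",
    "condition_ecg",
    "estimate_baseline",
    "detect_qrs",
    "rr_to_bpm",
    "match_beats",
]

REFRACTORY_S = 0.2
SEARCHBACK_FACTOR = 1.66
MWI_WINDOW_S = 0.15


def condition_ecg(ecg: Signal) -> Signal:
    """Software equivalent of the amplifier settings.

    Cascade of a 1 Hz 2nd-order Butterworth high-pass, a 35 Hz 4th-order
    low-pass and a Q = 30 notch at 50 Hz, all run causally.  Requires
    fs >= 200 Hz so the 35 Hz low-pass and mains notch are well inside
    Nyquist.
    """
    if ecg.fs < 200:
        raise ValueError(f"fs = {ecg.fs} Hz too low for the 35 Hz low-pass / 50 Hz notch chain")
    x = ecg.samples
    b, a = scipy.signal.butter(2, 1.0, btype="high", fs=ecg.fs)
    x = scipy.signal.lfilter(b, a, x)
    b, a = scipy.signal.butter(4, 35.0, btype="low", fs=ecg.fs)
    x = scipy.signal.lfilter(b, a, x)
    b, a = scipy.signal.iirnotch(50.0, Q=30.0, fs=ecg.fs)
    x = scipy.signal.lfilter(b, a, x)
    return ecg.with_samples(x)


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def estimate_baseline(ecg: Signal) -> Signal:
    """Slow baseline via cascaded median filters (200 ms then 600 ms).

    The first scale removes QRS complexes, the second removes T waves,
    leaving only sub-0.5 Hz wander.  Edge handling replicates the border
    sample, so a constant input returns itself exactly.
    """
    k1 = _odd(max(3, int(round(0.2 * ecg.fs))))
    k2 = _odd(max(3, int(round(0.6 * ecg.fs))))
    m = scipy.ndimage.median_filter(ecg.samples, size=k1, mode="nearest")
    m = scipy.ndimage.median_filter(m, size=k2, mode="nearest")
    return ecg.with_samples(m)


@dataclass(frozen=True)
class QrsResult:
    """Detected beats: R-peak indices, RR intervals, QRS durations, baseline."""

    r_peaks: np.ndarray
    rr_intervals: np.ndarray
    qrs_durations_ms: np.ndarray
    baseline: Signal


def _energy_envelope(x: np.ndarray, fs: float) -> np.ndarray:
    """Derivative -> squaring -> moving-window integration."""
    deriv = np.gradient(x)
    sq = deriv * deriv
    win = max(1, int(round(MWI_WINDOW_S * fs)))
    return np.convolve(sq, np.ones(win) / win, mode="same")


def _refine_peak(x: np.ndarray, idx: int, fs: float) -> int:
    """Locate the R peak as the signal maximum near an envelope peak."""
    lo = max(0, idx - int(round(0.10 * fs)))
    hi = min(x.size, idx + int(round(0.10 * fs)) + 1)
    return lo + int(np.argmax(x[lo:hi]))


def _qrs_duration_ms(x: np.ndarray, peak: int, fs: float) -> float:
    """QRS width from amplitude-threshold crossings around the R peak.

    The span of |x| above 15% of the R amplitude within +/-100 ms covers
    Q through S but excludes the isoelectric segments and the (much
    lower-slope) P and T waves.
    """
    half = int(round(0.1 * fs))
    lo = max(0, peak - half)
    hi = min(x.size, peak + half + 1)
    local = np.abs(x[lo:hi])
    thresh = 0.15 * abs(x[peak])
    above = local >= thresh
    if not above.any():
        return 0.0
    first = int(np.argmax(above))
    last = len(above) - 1 - int(np.argmax(above[::-1]))
    return (last - first) / fs * 1000.0


def detect_qrs(ecg: Signal, remove_baseline: bool = True) -> QrsResult:
    """Detect QRS complexes on a conditioned single-lead ECG.

    Candidate beats come from peaks of the derivative-energy envelope
    separated by at least the 200 ms refractory period; an adaptive
    signal/noise threshold (Pan–Tompkins-style running averages) accepts
    or rejects each candidate, and a search-back with a halved threshold
    recovers beats inside RR gaps longer than 1.66x the running median
    RR.  Requires at least 2 s of signal.
    """
    if ecg.duration_s < 2.0:
        raise ValueError("need at least 2 s of ECG to detect beats")
    baseline = estimate_baseline(ecg) if remove_baseline else ecg.with_samples(np.zeros(len(ecg)))
    x = ecg.samples - baseline.samples
    fs = ecg.fs
    env = _energy_envelope(x, fs)

    refractory = int(round(REFRACTORY_S * fs))
    cand, props = scipy.signal.find_peaks(env, distance=refractory)
    if cand.size == 0:
        return QrsResult(np.array([], int), np.array([], int), np.array([]), baseline)

    # Adaptive threshold seeded from the first two seconds.
    head = env[: int(2 * fs)]
    spk = float(head.max())
    npk = float(np.median(head))
    accepted: list[int] = []
    for idx in cand:
        thr = npk + 0.25 * (spk - npk)
        if env[idx] > thr:
            accepted.append(int(idx))
            spk = 0.125 * env[idx] + 0.875 * spk
        else:
            npk = 0.125 * env[idx] + 0.875 * npk

    # Search-back: re-examine long RR gaps with half the threshold.
    if len(accepted) >= 3:
        final: list[int] = [accepted[0]]
        rr_hist: list[int] = []
        for idx in accepted[1:]:
            rr_hist.append(idx - final[-1])
            median_rr = float(np.median(rr_hist))
            gap = idx - final[-1]
            if gap > SEARCHBACK_FACTOR * median_rr:
                thr = npk + 0.125 * (spk - npk)
                in_gap = cand[(cand > final[-1] + refractory) & (cand < idx - refractory)]
                if in_gap.size:
                    best = in_gap[np.argmax(env[in_gap])]
                    if env[best] > thr:
                        final.append(int(best))
            final.append(int(idx))
        accepted = final

    r_peaks = np.array(sorted({_refine_peak(x, i, fs) for i in accepted}), dtype=int)
    # Enforce refractory on the refined positions (keep the larger peak).
    if r_peaks.size:
        kept = [int(r_peaks[0])]
        for p in r_peaks[1:]:
            if p - kept[-1] < refractory:
                if x[p] > x[kept[-1]]:
                    kept[-1] = int(p)
            else:
                kept.append(int(p))
        r_peaks = np.array(kept, dtype=int)

    rr = np.diff(r_peaks)
    durations = np.array([_qrs_duration_ms(x, p, fs) for p in r_peaks])
    return QrsResult(r_peaks, rr, durations, baseline)


def rr_to_bpm(q: QrsResult, fs: float) -> np.ndarray:
    """Per-interval instantaneous rate: bpm = 60 * fs / RR."""
    if q.r_peaks.size < 2:
        raise ValueError("need at least two detected beats for a rate")
    return 60.0 * fs / q.rr_intervals


def match_beats(detected: np.ndarray, truth: np.ndarray, tol_samples: int):
    """Greedy one-to-one matching of detected beats to ground truth.

    Returns ``(n_matched, n_missed, n_false)`` within the tolerance.
    """
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    used = np.zeros(detected.size, dtype=bool)
    matched = 0
    for t in truth:
        if detected.size == 0:
            break
        j = int(np.argmin(np.abs(detected - t)))
        if not used[j] and abs(int(detected[j]) - int(t)) <= tol_samples:
            used[j] = True
            matched += 1
    return matched, truth.size - matched, int((~used).sum())
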