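"""Rule-based pre-diagnosis alerts over rate series and QRS measurements.

Four screening rules, all pure predicates over already-computed
quantities, with clinically conventional default thresholds:

* tachycardia above 130 bpm, bradycardia below 40 bpm (strict);
* rhythm variation: peak-to-peak spread above 20% of the window mean
  over a run of n consecutive complexes;
* up to nine missed QRS complexes per recording are acceptable;
* median QRS duration strictly above 120 ms.

A +/-10 bpm measurement error is regarded as admissible for the rate
estimates themselves; it is reported as metadata and deliberately does
not widen the alert thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AlertThresholds",
    "AlertReport",
    "check_rate_alerts",
    "check_variation_alert",
    "check_qrs_miss",
    "check_qrs_duration",
    "build_report",
]


@dataclass(frozen=True)
class AlertThresholds:
    tachy_bpm: float = 130.0
    brady_bpm: float = 40.0
    variation_fraction: float = 0.20
    max_qrs_misses: int = 9
    qrs_duration_ms: float = 120.0
    admitted_rate_error_bpm: float = 10.0


def check_rate_alerts(bpm_series, thresholds: AlertThresholds = AlertThresholds()):
    """Tachy/brady alerts: list of ``(index, kind)`` with strict thresholds."""
    series = list(bpm_series)
    if not series:
        raise ValueError("empty rate series")
    alerts = []
    for i, bpm in enumerate(series):
        if bpm > thresholds.tachy_bpm:
            alerts.append((i, "tachy"))
        elif bpm < thresholds.brady_bpm:
            alerts.append((i, "brady"))
    return alerts


def check_variation_alert(bpm_series, n_complexes: int, thresholds: AlertThresholds = AlertThresholds()):
    """Rhythm-variation alerts over runs of ``n_complexes`` values.

    A run ``[i, i + n)`` alerts when (max - min) / mean exceeds the
    variation fraction (default 20%).  Returns the list of offending
    ``(start, end)`` index pairs.
    """
    series = list(bpm_series)
    if n_complexes < 2:
        raise ValueError("n_complexes must be >= 2")
    if len(series) < n_complexes:
        raise ValueError(f"series of {len(series)} values shorter than run length {n_complexes}")
    alerts = []
    for i in range(len(series) - n_complexes + 1):
        run = series[i : i + n_complexes]
        mean = sum(run) / n_complexes
        if mean > 0 and (max(run) - min(run)) / mean > thresholds.variation_fraction:
            alerts.append((i, i + n_complexes))
    return alerts


def check_qrs_miss(expected: int, detected: int, thresholds: AlertThresholds = AlertThresholds()) -> bool:
    """True when the number of missed complexes is acceptable (<= 9)."""
    if detected > expected:
        raise ValueError("more detections than expected beats; reconcile false positives first")
    if detected < 0:
        raise ValueError("negative detection count")
    return (expected - detected) <= thresholds.max_qrs_misses


def _median(values) -> float:
    ordered = sorted(values)
    n = len(ordered)
    mid = n // 2
    if n % 2 == 1:
        return float(ordered[mid])
    return 0.5 * (ordered[mid - 1] + ordered[mid])


def check_qrs_duration(durations_ms, thresholds: AlertThresholds = AlertThresholds()) -> bool:
    """True (alert) when the median QRS duration strictly exceeds 120 ms."""
    values = list(durations_ms)
    if not values:
        raise ValueError("empty duration list")
    return _median(values) > thresholds.qrs_duration_ms


@dataclass(frozen=True)
class AlertReport:
    """Aggregate screening outcome; thresholds are echoed for traceability."""

    rate_alerts: list
    variation_alerts: list
    qrs_miss_acceptable: bool
    qrs_duration_alert: bool
    tolerances: AlertThresholds = field(default_factory=AlertThresholds)

    def to_dict(self) -> dict:
        return {
            "rate_alerts": [[i, kind] for i, kind in self.rate_alerts],
            "variation_alerts": [list(w) for w in self.variation_alerts],
            "qrs_miss_acceptable": bool(self.qrs_miss_acceptable),
            "qrs_duration_alert": bool(self.qrs_duration_alert),
            "tolerances": {
                "tachy_bpm": self.tolerances.tachy_bpm,
                "brady_bpm": self.tolerances.brady_bpm,
                "variation_fraction": self.tolerances.variation_fraction,
                "max_qrs_misses": self.tolerances.max_qrs_misses,
                "qrs_duration_ms": self.tolerances.qrs_duration_ms,
                "admitted_rate_error_bpm": self.tolerances.admitted_rate_error_bpm,
            },
        }


def build_report(
    bpm_series,
    expected_beats: int,
    detected_beats: int,
    qrs_durations_ms,
    n_complexes: int = 5,
    thresholds: AlertThresholds = AlertThresholds(),
) -> AlertReport:
    """Run all four rules and assemble a report."""
    series = list(bpm_series)
    variation = (
        check_variation_alert(series, n_complexes, thresholds)
        if len(series) >= n_complexes
        else []
    )
    return AlertReport(
        rate_alerts=check_rate_alerts(series, thresholds),
        variation_alerts=variation,
        qrs_miss_acceptable=check_qrs_miss(expected_beats, detected_beats, thresholds),
        qrs_duration_alert=check_qrs_duration(qrs_durations_ms, thresholds) if list(qrs_durations_ms) else False,
        tolerances=thresholds,
    )
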