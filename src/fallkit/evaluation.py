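"""Confusion-matrix metrics, two-stage pipeline evaluation, and the energy model.

Metrics follow the standard 2×2 tabulation with *fall* as the positive class:
accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
reported as percentages. A zero denominator raises instead of silently
returning 0, because a silent zero would corrupt small-suite reports.

The pipeline evaluator mirrors the deployed two-stage system: a trace whose
magnitude never exceeds 3 g is rejected at the threshold stage without any
radio traffic; a trace that triggers has its event window(s) confirmed or
rejected by the classifier. The energy model converts the measured per-state
current draws of the node into battery autonomy under duty cycling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .detector import DetectorConfig, detect_events_offline
from .errors import InvalidInputError, UndefinedMetricError
from .signals import AccelTrace, downsample
from .classifier import TrainedModel, classify


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Tabulate TP/TN/FP/FN with 1 = fall = positive class."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise InvalidInputError("labels and predictions must have equal length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise InvalidInputError("labels and predictions must be 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def accuracy(counts: ConfusionCounts) -> float:
    """100·(TP+TN)/(TP+TN+FP+FN)."""
    if counts.total == 0:
        raise UndefinedMetricError("accuracy undefined on an empty evaluation")
    return 100.0 * (counts.tp + counts.tn) / counts.total


def sensitivity(counts: ConfusionCounts) -> float:
    """100·TP/(TP+FN): the share of actual falls detected."""
    denom = counts.tp + counts.fn
    if denom == 0:
        raise UndefinedMetricError("sensitivity undefined without positive cases")
    return 100.0 * counts.tp / denom


def specificity(counts: ConfusionCounts) -> float:
    """100·TN/(TN+FP): the share of ADLs kept silent."""
    denom = counts.tn + counts.fp
    if denom == 0:
        raise UndefinedMetricError("specificity undefined without negative cases")
    return 100.0 * counts.tn / denom


@dataclass
class StageRow:
    """Per-activity two-stage breakdown (testbed-table layout)."""

    activity_code: str
    is_fall: bool
    n_traces: int = 0
    n_triggered: int = 0  # traces whose magnitude crossed 3 g
    n_classified_fall: int = 0  # traces the classifier confirmed as falls


@dataclass
class EvaluationReport:
    """Overall metrics plus per-activity rows; a metric whose class is absent
    from the suite (e.g. sensitivity of an all-ADL run) is ``None``."""

    counts: ConfusionCounts
    accuracy_pct: Optional[float]
    sensitivity_pct: Optional[float]
    specificity_pct: Optional[float]
    rows: List[StageRow] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "TP": self.counts.tp,
                "TN": self.counts.tn,
                "FP": self.counts.fp,
                "FN": self.counts.fn,
            },
            "accuracy_pct": None if self.accuracy_pct is None else round(self.accuracy_pct, 2),
            "sensitivity_pct": None
            if self.sensitivity_pct is None
            else round(self.sensitivity_pct, 2),
            "specificity_pct": None
            if self.specificity_pct is None
            else round(self.specificity_pct, 2),
            "rows": [
                {
                    "activity_code": r.activity_code,
                    "is_fall": r.is_fall,
                    "n_traces": r.n_traces,
                    "n_triggered": r.n_triggered,
                    "n_classified_fall": r.n_classified_fall,
                }
                for r in self.rows
            ],
        }

    def format_tables(self) -> str:
        """Human-readable two-stage tables, falls first then ADLs."""
        lines = []
        for fall_section in (True, False):
            rows = [r for r in self.rows if r.is_fall == fall_section]
            if not rows:
                continue
            if fall_section:
                lines.append("Falls: activity  n  presumed-by-threshold  confirmed-by-model")
            else:
                lines.append("ADLs:  activity  n  ignored-by-threshold   rejected-by-model")
            for r in rows:
                if fall_section:
                    lines.append(
                        f"  {r.activity_code:10s} {r.n_traces:3d}  "
                        f"{r.n_triggered:3d}  {r.n_classified_fall:3d}"
                    )
                else:
                    rejected = r.n_triggered - r.n_classified_fall
                    lines.append(
                        f"  {r.activity_code:10s} {r.n_traces:3d}  "
                        f"{r.n_traces - r.n_triggered:3d}  {rejected}/{r.n_triggered}"
                    )
        fmt = lambda v: "n/a" if v is None else f"{v:.2f}%"
        lines.append(
            f"accuracy {fmt(self.accuracy_pct)}  sensitivity {fmt(self.sensitivity_pct)}  "
            f"specificity {fmt(self.specificity_pct)}"
        )
        return "\n".join(lines)


def evaluate_pipeline(
    traces: Sequence[AccelTrace],
    model: TrainedModel,
    detector_config: Optional[DetectorConfig] = None,
) -> EvaluationReport:
    """Run the full two-stage system on labeled traces.

    Each trace is decimated to the detector rate, scanned by the threshold
    detector, and — only if a window was emitted — confirmed by the
    classifier (a trace counts as a predicted fall if any of its windows is
    classified as one). Fall traces that never cross the threshold are false
    negatives attributed to the threshold stage.
    """
    detector_config = detector_config or DetectorConfig()
    rows: Dict[str, StageRow] = {}
    labels, predictions = [], []
    for trace in traces:
        factor = trace.fs / detector_config.fs
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise InvalidInputError(
                f"trace rate {trace.fs} Hz is not an integer multiple of the "
                f"detector rate {detector_config.fs} Hz"
            )
        at_rate = downsample(trace, int(round(factor))) if factor > 1 else trace
        windows = detect_events_offline(at_rate.magnitude_series(), detector_config)
        triggered = len(windows) > 0
        predicted_fall = False
        if triggered:
            probs = [model.predict(w.values) for w in windows]
            predicted_fall = any(
                classify(p, model.config.decision_threshold) == 1 for p in probs
            )
        row = rows.setdefault(
            trace.activity_code, StageRow(trace.activity_code, trace.is_fall)
        )
        row.n_traces += 1
        row.n_triggered += int(triggered)
        row.n_classified_fall += int(predicted_fall)
        labels.append(int(trace.is_fall))
        predictions.append(int(predicted_fall))
    counts = confusion(labels, predictions)

    def _maybe(metric):
        try:
            return metric(counts)
        except UndefinedMetricError:
            return None

    return EvaluationReport(
        counts=counts,
        accuracy_pct=_maybe(accuracy),
        sensitivity_pct=_maybe(sensitivity),
        specificity_pct=_maybe(specificity),
        rows=sorted(rows.values(), key=lambda r: (not r.is_fall, r.activity_code)),
    )


@dataclass(frozen=True)
class EnergyProfile:
    """Measured per-state current draws of the sensor node (mA) and battery.

    The deployed duty cycle keeps the microcontroller asleep (waking only to
    sample at 20 Hz) with the radio suspended; transmission bursts last about
    12 s per event including retransmissions.
    """

    current_active_both_mA: float = 24.3
    current_mcu_active_radio_suspended_mA: float = 8.2
    current_sleep_mA: float = 4.5
    current_transmit_mA: float = 56.2
    battery_mAh: float = 1000.0
    usable_fraction: float = 0.80
    transmit_seconds_per_event: float = 12.0

    def __post_init__(self):
        if min(
            self.current_active_both_mA,
            self.current_mcu_active_radio_suspended_mA,
            self.current_sleep_mA,
            self.current_transmit_mA,
        ) <= 0:
            raise InvalidInputError("all currents must be positive")
        if not 0 < self.usable_fraction <= 1:
            raise InvalidInputError("usable_fraction must lie in (0, 1]")


def autonomy_hours(
    profile: EnergyProfile, average_current_mA: Optional[float] = None
) -> float:
    """Battery autonomy: usable capacity divided by average current draw.

    Defaults to the sleep-state current — the node's resting consumption under
    the deployed duty cycle (1000 mAh · 0.80 / 4.5 mA ≈ 178 h).
    """
    current = profile.current_sleep_mA if average_current_mA is None else average_current_mA
    if current <= 0:
        raise InvalidInputError("average current must be positive")
    return profile.battery_mAh * profile.usable_fraction / current


def consumption_reduction(reference_mA: float, reduced_mA: float) -> float:
    """Percentage reduction of ``reduced`` relative to ``reference``."""
    if reference_mA <= 0:
        raise InvalidInputError("reference current must be positive")
    return 100.0 * (reference_mA - reduced_mA) / reference_mA


def duty_cycle_average_current(
    profile: EnergyProfile, events_per_hour: float = 0.0
) -> float:
    """Average current with per-event transmit bursts folded in (mA).

    Scenario tool: sleep current plus ``events_per_hour`` bursts of
    ``transmit_seconds_per_event`` at the transmit current.
    """
    if events_per_hour < 0:
        raise InvalidInputError("events_per_hour must be non-negative")
    burst_s = events_per_hour * profile.transmit_seconds_per_event
    if burst_s > 3600:
        raise InvalidInputError("transmit bursts exceed one hour per hour")
    return (
        profile.current_sleep_mA * (3600 - burst_s)
        + profile.current_transmit_mA * burst_s
    ) / 3600.0
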