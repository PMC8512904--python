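"""Session-level motor-imagery performance metrics.

Accuracy is the fraction of scheduled active windows in which the beta
rebound crossed the calibrated threshold at least once:

    accuracy(%) = 100 · successful_attempts / total_attempts

where total attempts equals the number of scheduled active windows (not a
self-reported count).  Mean detection latency is averaged over detected
windows only, since latency is undefined for misses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rebound_detection import DetectionResult
from .session_protocol import Condition, ProtocolSchedule, active_windows

__all__ = ["SessionMetrics", "score_session", "compare_conditions", "metrics_table"]


@dataclass(frozen=True)
class SessionMetrics:
    successful_attempts: int
    total_attempts: int
    accuracy_pct: float
    mean_latency_ms: float | None
    rest_activation_count: int
    condition: Condition
    subject: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.successful_attempts <= self.total_attempts:
            raise ValueError("successful attempts must lie in [0, total]")
        expect = 100.0 * self.successful_attempts / self.total_attempts
        if not np.isclose(self.accuracy_pct, expect):
            raise ValueError("accuracy inconsistent with attempt counts")


def score_session(
    result: DetectionResult,
    schedule: ProtocolSchedule,
    subject: str | None = None,
) -> SessionMetrics:
    """Aggregate a detection result into session metrics."""
    n_windows = len(active_windows(schedule))
    if n_windows == 0:
        raise ValueError(
            f"schedule for {schedule.condition.value} has no active windows; "
            "accuracy is undefined"
        )
    if len(result.windows) != n_windows:
        raise ValueError(
            f"detection result covers {len(result.windows)} windows but the "
            f"schedule defines {n_windows}"
        )
    detected = result.n_detected
    lats = result.latencies_ms
    return SessionMetrics(
        successful_attempts=detected,
        total_attempts=n_windows,
        accuracy_pct=100.0 * detected / n_windows,
        mean_latency_ms=float(np.mean(lats)) if lats else None,
        rest_activation_count=len(result.rest_crossing_windows),
        condition=schedule.condition,
        subject=subject,
    )


def metrics_table(metrics: list[SessionMetrics]) -> pd.DataFrame:
    """One row per subject × condition (CSV-ready)."""
    return pd.DataFrame(
        {
            "subject": m.subject,
            "condition": m.condition.value,
            "successful_attempts": m.successful_attempts,
            "total_attempts": m.total_attempts,
            "accuracy_pct": m.accuracy_pct,
            "mean_latency_ms": m.mean_latency_ms,
            "rest_activations": m.rest_activation_count,
        }
        for m in metrics
    )


def compare_conditions(
    metrics: list[SessionMetrics],
    conditions: tuple[Condition, Condition] = (Condition.MIV, Condition.MIVH),
) -> pd.DataFrame:
    """Pair per-subject accuracies across two conditions.

    Returns one row per subject with both accuracies and their difference
    (second minus first), plus a final ``mean`` row; feeds the paired
    statistical comparison.  Every subject must appear in both conditions.
    """
    a, b = conditions
    by_subj: dict[str, dict[Condition, SessionMetrics]] = {}
    for m in metrics:
        if m.condition not in conditions:
            continue
        if m.subject is None:
            raise ValueError("paired comparison requires subject identifiers")
        by_subj.setdefault(m.subject, {})[m.condition] = m
    rows = []
    for subj, d in sorted(by_subj.items()):
        missing = [c.value for c in conditions if c not in d]
        if missing:
            raise ValueError(f"subject {subj!r} lacks condition(s): {missing}")
        rows.append(
            {
                "subject": subj,
                f"{a.value.lower()}_accuracy_pct": d[a].accuracy_pct,
                f"{b.value.lower()}_accuracy_pct": d[b].accuracy_pct,
                "difference_pct": d[b].accuracy_pct - d[a].accuracy_pct,
            }
        )
    if not rows:
        raise ValueError("no paired subjects found")
    df = pd.DataFrame(rows)
    mean_row = {"subject": "mean"} | {
        c: float(df[c].mean()) for c in df.columns if c != "subject"
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
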