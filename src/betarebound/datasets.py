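"""Published inputs from the five-participant T-FLEX BCI pilot.

These are the printed study inputs this pipeline was built around: the
QUEST satisfaction responses of the five stroke survivors, their
calibrated detection thresholds, and the per-condition mean detection
times and attempt counts.  They allow the scoring and reporting paths to
be exercised on real survey data without any recorded EEG (which was not
deposited).
"""

from __future__ import annotations

import pandas as pd

from .evaluation_stats import QUESTResponses

__all__ = [
    "pilot_quest_responses",
    "pilot_thresholds_uv2",
    "pilot_detection_times_ms",
    "pilot_attempt_rates",
]


def pilot_quest_responses() -> list[QUESTResponses]:
    """QUEST survey responses (1–5 Likert) of the five pilot participants."""
    core = {
        "S1": {"Dimensions": 4, "Weight": 5, "Adjustment": 5, "Safety": 5,
               "Ease of use": 5, "Effectiveness": 5,
               "Information/Instructions": 5},
        "S2": {"Dimensions": 5, "Weight": 5, "Adjustment": 5, "Safety": 5,
               "Ease of use": 5, "Effectiveness": 5,
               "Information/Instructions": 5},
        "S3": {"Dimensions": 3, "Weight": 5, "Adjustment": 4, "Safety": 4,
               "Ease of use": 5, "Effectiveness": 5,
               "Information/Instructions": 5},
        "S4": {"Dimensions": 4, "Weight": 5, "Adjustment": 5, "Safety": 5,
               "Ease of use": 4, "Effectiveness": 4,
               "Information/Instructions": 5},
        "S5": {"Dimensions": 5, "Weight": 5, "Adjustment": 5, "Safety": 5,
               "Ease of use": 5, "Effectiveness": 5,
               "Information/Instructions": 5},
    }
    extended = {
        "S1": {"Reliability": 5, "Speed": 4, "Learning": 4,
               "Aesthetic design": 4},
        "S2": {"Reliability": 5, "Speed": 4, "Learning": 5,
               "Aesthetic design": 5},
        "S3": {"Reliability": 4, "Speed": 4, "Learning": 5,
               "Aesthetic design": 4},
        "S4": {"Reliability": 5, "Speed": 4, "Learning": 5,
               "Aesthetic design": 5},
        "S5": {"Reliability": 5, "Speed": 4, "Learning": 5,
               "Aesthetic design": 5},
    }
    return [
        QUESTResponses(subject=s, scores=core[s] | extended[s]) for s in core
    ]


def pilot_thresholds_uv2() -> dict[str, float]:
    """Calibrated per-subject detection thresholds (µV² band power)."""
    return {"S1": 8.0, "S2": 8.0, "S3": 4.0, "S4": 20.0, "S5": 12.0}


def pilot_detection_times_ms() -> pd.DataFrame:
    """Mean first-crossing detection times per subject and condition."""
    return pd.DataFrame(
        {
            "subject": ["S1", "S2", "S3", "S4", "S5"],
            "MIV": [1798.0, 1272.0, 3326.0, 1226.0, 2418.0],
            "MIVH": [2116.0, 1173.0, 1646.0, 1010.0, 986.0],
        }
    )


def pilot_attempt_rates() -> dict[str, tuple[int, int]]:
    """Group-mean successful attempts over opportunities per MI condition.

    Visual stimulation averaged 8 detected windows of the 15 opportunities
    per capture; visual+haptic averaged 10 of 15.  Useful as presence
    probabilities when emulating cohorts with the synthetic generator.
    """
    return {"MIV": (8, 15), "MIVH": (10, 15)}
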