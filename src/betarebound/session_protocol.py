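"""Experimental session timelines for the BCI–exoskeleton protocol.

A recording session is a contiguous sequence of phases: an optional initial
WAIT period (system preparation, no commands accepted), followed by an
alternation of IDLE (rest) and ACTIVE (motor-imagery / movement) phases of
equal duration that runs until the session time is exhausted.  The
calibration capture is a single uninterrupted idle block during which the
participant remains static.

All times are seconds from recording start; phase intervals are half-open
``[start, start + duration)`` so every sample maps to exactly one phase.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field

__all__ = [
    "PhaseKind",
    "Stimulus",
    "Condition",
    "Phase",
    "ProtocolSchedule",
    "build_schedule",
    "preset_schedule",
    "active_windows",
    "idle_windows",
]


class PhaseKind(str, enum.Enum):
    WAIT = "WAIT"
    IDLE = "IDLE"
    ACTIVE = "ACTIVE"


class Stimulus(str, enum.Enum):
    NONE = "NONE"
    VISUAL = "VISUAL"
    VISUAL_HAPTIC = "VISUAL_HAPTIC"


class Condition(str, enum.Enum):
    """The five captures of a session.

    CALIBRATION fixes the detection threshold; FREE_MOVE (unassisted ankle
    movement) and ST (stationary therapy, exoskeleton moves on a timer)
    familiarize the participant; MIV and MIVH are the motor-imagery captures
    with visual and visual+haptic stimulation respectively.
    """

    CALIBRATION = "CALIBRATION"
    FREE_MOVE = "FREE_MOVE"
    ST = "ST"
    MIV = "MIV"
    MIVH = "MIVH"


#: Stimulus delivered during ACTIVE phases, per condition.
CONDITION_STIMULUS = {
    Condition.CALIBRATION: Stimulus.NONE,
    Condition.FREE_MOVE: Stimulus.NONE,
    Condition.ST: Stimulus.NONE,
    Condition.MIV: Stimulus.VISUAL,
    Condition.MIVH: Stimulus.VISUAL_HAPTIC,
}


@dataclass(frozen=True)
class Phase:
    kind: PhaseKind
    start: float
    duration: float
    stimulus: Stimulus = Stimulus.NONE

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"phase duration must be positive, got {self.duration}")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ProtocolSchedule:
    condition: Condition
    phases: tuple[Phase, ...]
    total_duration: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("schedule must contain at least one phase")
        t = 0.0
        for ph in self.phases:
            if not math.isclose(ph.start, t, abs_tol=1e-9):
                raise ValueError(
                    f"phases must be contiguous: expected start {t}, got {ph.start}"
                )
            t = ph.end
        if self.total_duration == 0.0:
            object.__setattr__(self, "total_duration", t)
        elif not math.isclose(t, self.total_duration, abs_tol=1e-9):
            raise ValueError(
                f"phase durations sum to {t}, not total_duration={self.total_duration}"
            )

    def phase_at(self, t: float) -> Phase | None:
        """Phase whose half-open interval contains time ``t``, or None."""
        for ph in self.phases:
            if ph.start <= t < ph.end:
                return ph
        return None

    def phases_of(self, kind: PhaseKind) -> list[Phase]:
        return [ph for ph in self.phases if ph.kind is kind]

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "condition": self.condition.value,
            "phases": [
                {
                    "kind": ph.kind.value,
                    "start": ph.start,
                    "duration": ph.duration,
                    "stimulus": ph.stimulus.value,
                }
                for ph in self.phases
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSchedule":
        phases = tuple(
            Phase(
                kind=PhaseKind(p["kind"]),
                start=float(p["start"]),
                duration=float(p["duration"]),
                stimulus=Stimulus(p.get("stimulus", "NONE")),
            )
            for p in d["phases"]
        )
        return cls(condition=Condition(d["condition"]), phases=phases)

    @classmethod
    def from_json(cls, path) -> "ProtocolSchedule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_schedule(
    condition: Condition | str,
    total_duration: float = 300.0,
    wait: float = 30.0,
    phase_duration: float = 10.0,
    first_phase: PhaseKind | str = PhaseKind.ACTIVE,
) -> ProtocolSchedule:
    """Build a session timeline.

    After the initial WAIT of ``wait`` seconds, IDLE and ACTIVE phases of
    ``phase_duration`` seconds alternate, starting with ``first_phase``.
    Only whole phases that fit within ``total_duration`` are emitted; if a
    partial phase would remain, the schedule simply ends at the last whole
    phase and ``total_duration`` is shortened accordingly, so the phases
    always tile ``[0, total_duration)`` exactly.

    For CALIBRATION the timeline is a single idle block of the full
    duration, during which the participant remains static.
    """
    condition = Condition(condition)
    first_phase = PhaseKind(first_phase)
    if total_duration <= 0:
        raise ValueError(f"total_duration must be positive, got {total_duration}")
    if phase_duration <= 0:
        raise ValueError(f"phase_duration must be positive, got {phase_duration}")
    if wait < 0:
        raise ValueError(f"wait must be non-negative, got {wait}")
    if total_duration < wait:
        raise ValueError(
            f"total_duration ({total_duration}) must be at least wait ({wait})"
        )
    if first_phase not in (PhaseKind.ACTIVE, PhaseKind.IDLE):
        raise ValueError("first_phase must be ACTIVE or IDLE")

    if condition is Condition.CALIBRATION:
        phases = (Phase(PhaseKind.IDLE, 0.0, total_duration),)
        return ProtocolSchedule(condition, phases, total_duration)

    stimulus = CONDITION_STIMULUS[condition]
    phases: list[Phase] = []
    t = 0.0
    if wait > 0:
        phases.append(Phase(PhaseKind.WAIT, 0.0, wait))
        t = wait
    kind = first_phase
    while t + phase_duration <= total_duration + 1e-9:
        stim = stimulus if kind is PhaseKind.ACTIVE else Stimulus.NONE
        phases.append(Phase(kind, t, phase_duration, stim))
        t += phase_duration
        kind = PhaseKind.IDLE if kind is PhaseKind.ACTIVE else PhaseKind.ACTIVE
    if not phases:
        raise ValueError("no whole phase fits within total_duration after wait")
    return ProtocolSchedule(condition, tuple(phases), t)


#: Named presets.  "default" mirrors the study timeline (30 s wait, then
#: 10 s idle/active alternation over 5 min → 14 active windows); "no_wait"
#: drops the modeled wait so all 15 opportunities of a 5-min capture appear.
_PRESETS = {
    "default": dict(total_duration=300.0, wait=30.0, phase_duration=10.0,
                    first_phase=PhaseKind.ACTIVE),
    "no_wait": dict(total_duration=300.0, wait=0.0, phase_duration=10.0,
                    first_phase=PhaseKind.IDLE),
    "calibration": dict(total_duration=300.0, wait=0.0, phase_duration=300.0,
                        first_phase=PhaseKind.IDLE),
}


def preset_schedule(name: str = "default",
                    condition: Condition | str = Condition.MIV) -> ProtocolSchedule:
    """A named session preset; ``calibration`` forces the CALIBRATION condition."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    if name == "calibration":
        condition = Condition.CALIBRATION
    return build_schedule(condition, **_PRESETS[name])


def active_windows(schedule: ProtocolSchedule) -> list[tuple[float, float]]:
    """ACTIVE phases as half-open ``[start, end)`` intervals, in time order."""
    return [ph.interval for ph in schedule.phases_of(PhaseKind.ACTIVE)]


def idle_windows(schedule: ProtocolSchedule) -> list[tuple[float, float]]:
    """IDLE phases as half-open ``[start, end)`` intervals, in time order."""
    return [ph.interval for ph in schedule.phases_of(PhaseKind.IDLE)]
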