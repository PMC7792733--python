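"""Cardiac-cycle phase segmentation from valve events and ECG landmarks.

One heartbeat is delimited by the onsets of two consecutive QRS complexes.
Between them, the four valve events (mitral closure MVC, aortic opening
AVO, aortic closure AVC, mitral opening MVO) and the P-wave onset split the
cycle into six mechanical phases, in order of occurrence:

=====  =============================  ===================
label  phase                          interval
=====  =============================  ===================
EMC    electromechanical coupling     [QRS1, MVC)
IVC    isovolumic contraction         [MVC, AVO)
Ejec   ejection                       [AVO, AVC)
IVR    isovolumic relaxation          [AVC, MVO)
E      early (rapid) filling          [MVO, P onset)
A      atrial contraction             [P onset, QRS2)
=====  =============================  ===================

Intervals are half-open so every instant of the cycle belongs to exactly
one phase and the six durations sum to the cycle length exactly.  Diastasis
is not separated from early filling because the only intra-diastolic ECG
landmark collected is the P-wave onset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields

from .errors import EventOrderError, UsageError

PHASE_ORDER = ("EMC", "IVC", "Ejec", "IVR", "E", "A")

#: event names in their physiological order within one cycle
EVENT_ORDER = ("qrs1", "mvc", "avo", "avc", "mvo", "p_onset", "qrs2")


@dataclass(frozen=True)
class EventTiming:
    """Valve events and ECG landmarks of one cardiac cycle, in ms.

    Times share one clock with the strain trace; by convention t = 0 at the
    first QRS onset.  The physiological ordering
    ``qrs1 <= mvc < avo < avc < mvo < p_onset < qrs2`` is enforced at
    construction; ``qrs1 == mvc`` is permitted as a degenerate (zero-length)
    electromechanical-coupling phase.
    """

    qrs1: float
    mvc: float
    avo: float
    avc: float
    mvo: float
    p_onset: float
    qrs2: float

    def __post_init__(self) -> None:
        seq = [(name, getattr(self, name)) for name in EVENT_ORDER]
        # qrs1 <= mvc, all later pairs strict
        for (n0, t0), (n1, t1) in itertools.pairwise(seq):
            ok = t0 <= t1 if (n0, n1) == ("qrs1", "mvc") else t0 < t1
            if not ok:
                raise EventOrderError(
                    f"event ordering '{n0} < {n1}' violated: "
                    f"{n0}={t0:g} ms, {n1}={t1:g} ms"
                )

    def shifted(self, dt: float) -> "EventTiming":
        """Return the same cycle with all times shifted by ``dt`` ms."""
        return EventTiming(**{f.name: getattr(self, f.name) + dt for f in fields(self)})

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in EVENT_ORDER}

    @property
    def cycle_length(self) -> float:
        """RR interval of the selected beat, ms."""
        return self.qrs2 - self.qrs1


@dataclass(frozen=True)
class CyclePhases:
    """The six mechanical phases of one cycle as half-open intervals [start, end), ms."""

    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.intervals) != PHASE_ORDER:
            raise UsageError(f"phases must be exactly {PHASE_ORDER} in order")

    @property
    def durations(self) -> dict[str, float]:
        return {k: end - start for k, (start, end) in self.intervals.items()}

    @property
    def starts(self) -> dict[str, float]:
        return {k: start for k, (start, _) in self.intervals.items()}

    def phase_of(self, t: float) -> str | None:
        """Phase containing time ``t``, or None outside the cycle."""
        for name, (start, end) in self.intervals.items():
            if start <= t < end:
                return name
        return None

    def format_report(self) -> str:
        """Human-readable phase table (start / duration per phase)."""
        lines = ["phase  start_ms  duration_ms"]
        for name, (start, end) in self.intervals.items():
            lines.append(f"{name:<5s}  {start:8.1f}  {end - start:11.1f}")
        return "\n".join(lines)


def segment_phases(events: EventTiming) -> CyclePhases:
    """Partition the cycle [qrs1, qrs2) into the six mechanical phases.

    Parameters
    ----------
    events
        Validated event set for one cycle.

    Returns
    -------
    CyclePhases
        Contiguous half-open intervals whose durations sum exactly to the
        cycle length.
    """
    e = events
    bounds = (e.qrs1, e.mvc, e.avo, e.avc, e.mvo, e.p_onset, e.qrs2)
    return CyclePhases(
        {
            name: (bounds[i], bounds[i + 1])
            for i, name in enumerate(PHASE_ORDER)
        }
    )


def validate_landmarks(
    ecg: "EcgTrace", qrs1: float, p_onset: float, qrs2: float
) -> dict[str, float]:
    """Check three ECG landmark times against an ECG trace.

    The marks must be ordered ``qrs1 < p_onset < qrs2`` and all lie within
    the recorded span of the ECG.  Returns the landmark fields ready to be
    merged into an :class:`EventTiming`.
    """
    t0, t1 = float(ecg.time[0]), float(ecg.time[-1])
    for name, t in (("qrs1", qrs1), ("p_onset", p_onset), ("qrs2", qrs2)):
        if not (t0 <= t <= t1):
            raise EventOrderError(
                f"landmark {name}={t:g} ms outside ECG span [{t0:g}, {t1:g}] ms"
            )
    if not (qrs1 < p_onset < qrs2):
        raise EventOrderError(
            f"landmarks misordered: need qrs1 < p_onset < qrs2, "
            f"got ({qrs1:g}, {p_onset:g}, {qrs2:g})"
        )
    return {"qrs1": qrs1, "p_onset": p_onset, "qrs2": qrs2}


@dataclass(frozen=True)
class EventConsistency:
    """Outcome of the repeated-registration timing check."""

    max_diff: dict[str, float]  #: max pairwise |difference| per event, ms
    event_ok: dict[str, bool]
    tol: float

    @property
    def passed(self) -> bool:
        return all(self.event_ok.values())


def check_event_timing_consistency(
    registrations: list[EventTiming], tol: float = 10.0
) -> EventConsistency:
    """Quality-control check across repeated event registrations of one exam.

    Exams whose recorded event times disagree by more than ``tol`` ms
    (default 10 ms) between registrations are flagged for exclusion.

    Parameters
    ----------
    registrations
        Two or more :class:`EventTiming` recorded for the same exam.
    tol
        Maximum tolerated pairwise absolute difference per event, ms.
    """
    if len(registrations) < 2:
        raise UsageError("consistency check needs at least two registrations")
    max_diff: dict[str, float] = {}
    for name in EVENT_ORDER:
        values = [getattr(r, name) for r in registrations]
        max_diff[name] = max(abs(x - y) for x, y in itertools.combinations(values, 2))
    event_ok = {name: diff <= tol for name, diff in max_diff.items()}
    return EventConsistency(max_diff=max_diff, event_ok=event_ok, tol=tol)
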