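"""Discrete-event kernel and the victim monitoring model.

The kernel is a deterministic heap-based event queue: events execute in
``(time, sequence)`` order, where the sequence number is assigned at
scheduling time, so simultaneous events fire in scheduling order.  Time is
continuous (real minutes).

The :class:`ClinicalMonitor` drives each victim's clinical state machine: it
keeps exactly one pending time transition per victim and, when a treatment is
delivered, cancels it and reschedules the state change onto the treatment
pathway after the transition's treatment-effect delay.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

from .victim import matching_transition

EVENT_KINDS = (
    "cc_time_transition",
    "treatment_complete",
    "triage_complete",
    "vehicle_arrival",
    "vehicle_departure",
    "loading_complete",
    "sar_extraction",
    "admission",
    "dispatch_wave",
)

LOG_FORMAT_VERSION = 1


class SchedulingError(RuntimeError):
    pass


@dataclass
class Handle:
    time: float
    seq: int
    kind: str
    subject: str
    callback: object
    detail: dict
    cancelled: bool = False
    fired: bool = False


@dataclass(frozen=True)
class LogRecord:
    time: float
    kind: str
    subject: str
    detail: tuple  # sorted (key, value) pairs

    def line(self) -> str:
        d = ";".join(f"{k}={v}" for k, v in self.detail)
        return f"{self.time:.3f}\t{self.kind}\t{self.subject}\t{d}"


class EventLog:
    """Append-only record of executed events and their state deltas."""

    def __init__(self):
        self.records: list[LogRecord] = []

    def record(self, time, kind, subject, **detail):
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        if self.records and time < self.records[-1].time - 1e-9:
            raise ValueError("log times must be non-decreasing")
        self.records.append(
            LogRecord(float(time), kind, str(subject), tuple(sorted(detail.items())))
        )

    def lines(self):
        yield f"# mcisim-eventlog v{LOG_FORMAT_VERSION}"
        for r in self.records:
            yield r.line()

    def write(self, path):
        with open(path, "w") as fh:
            for line in self.lines():
                fh.write(line + "\n")

    def filter(self, kind=None, subject=None):
        return [
            r
            for r in self.records
            if (kind is None or r.kind == kind)
            and (subject is None or r.subject == subject)
        ]

    def first(self, kind=None, subject=None, **detail_match):
        for r in self.records:
            if kind and r.kind != kind:
                continue
            if subject and r.subject != subject:
                continue
            d = dict(r.detail)
            if all(d.get(k) == v for k, v in detail_match.items()):
                return r
        return None


class Scheduler:
    """Deterministic event queue with (time, sequence) ordering."""

    def __init__(self, log: EventLog | None = None):
        self.now = 0.0
        self.log = log if log is not None else EventLog()
        self._heap: list = []
        self._seq = 0

    def schedule(self, at, kind, subject, callback=None, **detail) -> Handle:
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        if at < self.now - 1e-9:
            raise SchedulingError(f"cannot schedule at {at} before clock {self.now}")
        self._seq += 1
        h = Handle(float(at), self._seq, kind, str(subject), callback, dict(detail))
        heapq.heappush(self._heap, (h.time, h.seq, h))
        return h

    def cancel(self, handle: Handle) -> None:
        if handle.cancelled:
            raise SchedulingError("event already cancelled")
        if handle.fired:
            raise SchedulingError("event already fired")
        handle.cancelled = True

    def run_until(self, t_end=math.inf) -> EventLog:
        while self._heap:
            t, _, h = self._heap[0]
            if t > t_end:
                break
            heapq.heappop(self._heap)
            if h.cancelled:
                continue
            self.now = t
            h.fired = True
            self.log.record(t, h.kind, h.subject, **h.detail)
            if h.callback is not None:
                h.callback()
        if math.isfinite(t_end):
            self.now = max(self.now, t_end)
        return self.log


class ClinicalMonitor:
    """Adapts victims' health states via time and treatment triggers."""

    def __init__(self, scheduler: Scheduler, on_death=None, on_condition_change=None):
        self.sched = scheduler
        self.on_death = on_death
        self.on_condition_change = on_condition_change
        self._pending: dict[str, Handle] = {}

    # -- registration -------------------------------------------------------
    def register(self, entity) -> None:
        """Start monitoring: schedule the initial pending time transition."""
        entity.clinical.on_treatment = lambda skill: self._treatment(entity, skill)
        self._schedule_time(entity)

    def _schedule_time(self, entity) -> None:
        cc = entity.current_condition()
        if cc.is_end_state:
            return
        tr = entity.profile.time_transition(cc.condition_id)
        h = self.sched.schedule(
            self.sched.now + tr.delay,
            "cc_time_transition",
            entity.victim_id,
            lambda: self._fire(entity, tr.target, trigger="time"),
            enter=tr.target,
        )
        self._pending[entity.victim_id] = h

    # -- trigger handling ---------------------------------------------------
    def _fire(self, entity, target, trigger) -> None:
        cc = entity.current_condition()
        assert not cc.is_end_state, "time trigger fired on an end state"
        self._pending.pop(entity.victim_id, None)
        entity.set_condition(target)
        new = entity.current_condition()
        if new.end_kind == "dead":
            entity.clinical.notify_death(self.sched.now)
            if self.on_death is not None:
                self.on_death(entity)
            return
        if self.on_condition_change is not None:
            self.on_condition_change(entity)
        if not new.is_end_state:
            self._schedule_time(entity)

    def _treatment(self, entity, skill) -> None:
        """Treatment delivered: switch to the treatment pathway.

        The pending untreated transition is cancelled immediately; the state
        change onto the new pathway fires after the transition's
        treatment-effect delay.
        """
        if not entity.alive:
            self.sched.log.record(
                self.sched.now,
                "treatment_complete",
                entity.victim_id,
                warning="treatment on dead victim ignored",
                skill=skill,
            )
            return
        cc = entity.current_condition()
        if cc.is_end_state:
            return  # stabilized victims no longer evolve
        tr = matching_transition(cc.condition_id, skill, entity.profile)
        if tr is None:
            return  # no pathway for this skill from here
        old = self._pending.pop(entity.victim_id, None)
        if old is not None and not old.fired and not old.cancelled:
            self.sched.cancel(old)
        h = self.sched.schedule(
            self.sched.now + tr.delay,
            "cc_time_transition",
            entity.victim_id,
            lambda: self._fire(entity, tr.target, trigger="treatment"),
            enter=tr.target,
            trigger="treatment",
            skill=skill,
        )
        self._pending[entity.victim_id] = h
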