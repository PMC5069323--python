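"""Victim data model.

A victim is described by a *profile*: a directed graph of clinical conditions
(health states) connected by transitions.  Time transitions form the untreated
pathway (the states the victim passes through if nobody intervenes, ending in
death or a stable state); treatment transitions branch onto treatment pathways
according to the skill level of the provider (EMT < PIT < MMT < ED).

Injury severity is summarised by the RPM score: the sum of coded respiratory
rate, pulse rate and best motor response, an integer from 0 (worst) to 12.
Triage categories follow the NATO T1 (immediate) .. T4 (expectant) scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .tables import MOTOR_LEVELS, RPM_CODING, RPM_MAX, RPM_MIN, DeteriorationTable

TRIAGE_CATEGORIES = ("T1", "T2", "T3", "T4")
SKILLS = ("EMT", "PIT", "MMT", "ED")
SKILL_RANK = {s: i for i, s in enumerate(SKILLS, start=1)}
END_KINDS = ("none", "dead", "stabilized")

ARRIVAL_LIMIT = 1000  # priority code reserves 3 decimal digits for the arrival minute


class ProfileValidationError(ValueError):
    """A victim profile violates the state-machine contract."""


class PriorityOverflowError(ValueError):
    """Arrival minute does not fit in the 3-digit priority-code field."""


def _code_from_ranges(value: int, ranges, what: str) -> int:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise ValueError(f"{what} must be an integer, got {value!r}")
    if value < 0:
        raise ValueError(f"{what} must be >= 0, got {value}")
    for lo, hi, code in ranges:
        if lo <= value <= hi:
            return code
    raise ValueError(f"{what} {value} matches no coding range")


def code_respiratory_rate(rr: int) -> int:
    """Coded respiratory rate: 0->0; 1-9->1; 36+->2; 25-35->3; 10-24->4."""
    return _code_from_ranges(rr, RPM_CODING["rr"], "respiratory rate")


def code_pulse_rate(pr: int) -> int:
    """Coded pulse rate: 0->0; 1-40->1; 41-60->2; 121+->3; 61-120->4."""
    return _code_from_ranges(pr, RPM_CODING["pr"], "pulse rate")


def code_motor_response(m: str) -> int:
    """Coded best motor response (none .. obeys -> 0 .. 4)."""
    try:
        return RPM_CODING["motor"][m]
    except KeyError:
        raise ValueError(f"unknown motor response {m!r}; expected one of {MOTOR_LEVELS}")


@dataclass(frozen=True)
class VitalSigns:
    respiratory_rate: int
    pulse_rate: int
    motor_response: str

    def __post_init__(self):
        code_respiratory_rate(self.respiratory_rate)
        code_pulse_rate(self.pulse_rate)
        code_motor_response(self.motor_response)


def rpm_score(v: VitalSigns) -> int:
    """RPM score: sum of the three coded vital values, in [0, 12]."""
    return (
        code_respiratory_rate(v.respiratory_rate)
        + code_pulse_rate(v.pulse_rate)
        + code_motor_response(v.motor_response)
    )


def survival_probability(rpm: int, t: float, table: DeteriorationTable) -> float:
    """Survival probability in percent at elapsed time ``t`` for an RPM score."""
    return table.lookup(rpm, t)


def priority_code(category: int, rpm: int, arrival: int) -> int:
    """Priority code: category*100000 + rpm*1000 + arrival minute.

    Lower code = higher priority for treatment and evacuation.  The arrival
    field is fixed at three decimal digits, so arrivals at or beyond minute
    1000 cannot be encoded and raise :class:`PriorityOverflowError`.
    """
    if category not in (1, 2, 3, 4):
        raise ValueError(f"triage category must be 1..4, got {category!r}")
    if not (RPM_MIN <= rpm <= RPM_MAX):
        raise ValueError(f"RPM score must be 0..12, got {rpm!r}")
    if arrival < 0:
        raise ValueError("arrival minute must be >= 0")
    if arrival >= ARRIVAL_LIMIT:
        raise PriorityOverflowError(
            f"arrival minute {arrival} overflows the 3-digit priority-code field"
        )
    return category * 100000 + rpm * 1000 + int(arrival)


@dataclass(frozen=True)
class ClinicalCondition:
    """One health state: vitals, derived scores and end-state flags."""

    condition_id: str
    vitals: VitalSigns
    rpm: int
    triage_category: str
    is_end_state: bool = False
    end_kind: str = "none"

    def __post_init__(self):
        if self.rpm != rpm_score(self.vitals):
            raise ValueError(
                f"condition {self.condition_id}: rpm {self.rpm} does not equal the "
                f"coded sum {rpm_score(self.vitals)}"
            )
        if self.triage_category not in TRIAGE_CATEGORIES:
            raise ValueError(f"unknown triage category {self.triage_category!r}")
        if self.end_kind not in END_KINDS:
            raise ValueError(f"unknown end kind {self.end_kind!r}")
        if self.is_end_state != (self.end_kind != "none"):
            raise ValueError("is_end_state must hold exactly when end_kind != 'none'")

    @classmethod
    def from_vitals(cls, condition_id, vitals, triage_category, end_kind="none"):
        return cls(
            condition_id=condition_id,
            vitals=vitals,
            rpm=rpm_score(vitals),
            triage_category=triage_category,
            is_end_state=end_kind != "none",
            end_kind=end_kind,
        )


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    trigger_kind: str  # "time" | "treatment"
    delay: float  # minutes: dwell (time) or treatment-effect time (treatment)
    required_skill: str = "none"
    required_supplies: tuple = ()

    def __post_init__(self):
        if self.trigger_kind not in ("time", "treatment"):
            raise ValueError(f"unknown trigger kind {self.trigger_kind!r}")
        if self.delay <= 0:
            raise ValueError("transition delay must be > 0 minutes")
        if self.trigger_kind == "treatment":
            if self.required_skill not in SKILLS:
                raise ValueError("treatment transitions need a skill in EMT/PIT/MMT/ED")
        elif self.required_skill != "none":
            raise ValueError("time transitions must not require a skill")


@dataclass
class VictimProfile:
    victim_id: str
    triage_mix_category: str
    ambulatory: bool
    destination_need: str  # general | trauma_centre | burn_centre
    initial_condition: str
    conditions: dict = field(default_factory=dict)  # condition_id -> ClinicalCondition
    transitions: list = field(default_factory=list)

    # -- indexing -----------------------------------------------------------
    def _index(self):
        idx = {}
        for tr in self.transitions:
            key = (tr.source, tr.trigger_kind, tr.required_skill)
            if key in idx:
                raise ProfileValidationError(
                    f"profile {self.victim_id}: duplicate transition {key}"
                )
            idx[key] = tr
        return idx

    def time_transition(self, condition_id: str):
        return self._index().get((condition_id, "time", "none"))

    def validate(self) -> None:
        """Check the full state-machine contract; raise on first violation."""
        if self.triage_mix_category not in TRIAGE_CATEGORIES:
            raise ProfileValidationError(f"bad category {self.triage_mix_category!r}")
        if self.destination_need not in ("general", "trauma_centre", "burn_centre"):
            raise ProfileValidationError(f"bad destination {self.destination_need!r}")
        if self.initial_condition not in self.conditions:
            raise ProfileValidationError("initial condition missing from conditions")
        idx = self._index()
        for tr in self.transitions:
            if tr.source not in self.conditions or tr.target not in self.conditions:
                raise ProfileValidationError(f"dangling transition {tr.source}->{tr.target}")
            if self.conditions[tr.source].end_kind == "dead":
                raise ProfileValidationError("dead states must have no outgoing transitions")
        # the untreated pathway must be total: every non-end condition has a
        # time transition, and the time-transition graph is acyclic
        for cid, cc in self.conditions.items():
            if not cc.is_end_state and (cid, "time", "none") not in idx:
                raise ProfileValidationError(
                    f"non-end condition {cid} lacks a time transition (CCt not total)"
                )
        seen, cur = set(), self.initial_condition
        while not self.conditions[cur].is_end_state:
            if cur in seen:
                raise ProfileValidationError("cycle in the untreated time pathway")
            seen.add(cur)
            cur = idx[(cur, "time", "none")].target

    # -- queries ------------------------------------------------------------
    def condition(self, condition_id: str) -> ClinicalCondition:
        return self.conditions[condition_id]


def next_condition(current: str, trigger_kind: str, skill, profile: VictimProfile):
    """Target condition of the unique matching transition, or ``None``.

    Treatment triggers match on the provider's skill.  If no transition is
    dedicated to that skill, a higher-skilled provider may fire the
    highest-ranked lower-skill transition available (MMT covers PIT covers
    EMT, ED covers all): escalation is never blocked by over-qualification.
    """
    idx = profile._index()
    if trigger_kind == "time":
        tr = idx.get((current, "time", "none"))
        return tr.target if tr else None
    if skill not in SKILLS:
        raise ValueError(f"unknown skill {skill!r}")
    tr = idx.get((current, "treatment", skill))
    if tr is None:
        rank = SKILL_RANK[skill]
        candidates = [
            idx[(current, "treatment", s)]
            for s in SKILLS
            if SKILL_RANK[s] < rank and (current, "treatment", s) in idx
        ]
        tr = max(candidates, key=lambda t: SKILL_RANK[t.required_skill], default=None)
    return tr.target if tr else None


def matching_transition(current: str, skill: str, profile: VictimProfile):
    """The transition :func:`next_condition` would fire, or ``None``."""
    idx = profile._index()
    tr = idx.get((current, "treatment", skill))
    if tr is None:
        rank = SKILL_RANK[skill]
        candidates = [
            idx[(current, "treatment", s)]
            for s in SKILLS
            if SKILL_RANK[s] < rank and (current, "treatment", s) in idx
        ]
        tr = max(candidates, key=lambda t: SKILL_RANK[t.required_skill], default=None)
    return tr


def untreated_death_time(profile: VictimProfile, table=None) -> float:
    """Clock time at which the untreated pathway enters a dead state.

    Walks the time-trigger pathway from the initial condition accumulating
    dwell times.  Returns ``math.inf`` ("never") when the pathway terminates
    in a stabilized or otherwise non-lethal end state.
    """
    profile.validate()
    idx = profile._index()
    t, cur = 0.0, profile.initial_condition
    while True:
        cc = profile.conditions[cur]
        if cc.end_kind == "dead":
            return t
        if cc.is_end_state:
            return math.inf
        tr = idx[(cur, "time", "none")]
        t += tr.delay
        cur = tr.target
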