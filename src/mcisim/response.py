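"""Medical response model: service points, SAR, dispatch, triage, treatment,
evacuation and hospital admission.

The response choreography follows the airport medical intervention plan:

* t=0 crash; initial dispatch of 5 BLS ambulances, 4 mobile medical teams
  (MMTs, one acting as on-scene commander who never treats or transports) and
  2 Red Cross rapid intervention teams (RITs).
* Walking wounded reach the casualty collection point (CCP) by minute 3;
  search-and-rescue extraction of non-ambulatory victims starts at minute 5
  and speeds up when extra holes are cut in the fuselage at minute 21.
* The second MMT triages at the CCP; the third and fourth set up the forward
  medical post (FMP), where treatment can start 8 minutes after their
  arrival.  The CCP->FMP leg takes 1 minute.
* Under stay-and-play, urgent victims are shuttled CCP->FMP, stabilized, then
  evacuated to hospitals; under scoop-and-run they are evacuated directly
  from the CCP with care en route per the supervising crew's skill.
* Each ambulance carries exactly one urgent patient, pickup assignments are
  never preempted, and a victim's simulation terminates on ED admission.
"""

from __future__ import annotations

import dataclasses
import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .engine import ClinicalMonitor, EventLog, Scheduler
from .scenario import Scenario, VictimEntity, category_for_rpm
from .victim import priority_code

POLICIES = ("scoop_and_run", "stay_and_play")
SAR_LEVELS = ("low", "medium", "high")
RESOURCE_LEVELS = ("low", "medium", "normal", "high")
SUPERVISION_LEVELS = ("emt", "nurse", "best_available", "physician_nurse")
DISTRIBUTIONS = ("nearest_first", "round_robin")
HCF_LEVELS = ("low", "medium", "high")


def travel_time(distance_km: float, speed_kmh: float) -> float:
    """Travel time in minutes: distance / speed * 60."""
    if distance_km < 0:
        raise ValueError("distance must be >= 0")
    if speed_kmh <= 0:
        raise ValueError("speed must be > 0")
    return distance_km / speed_kmh * 60.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ResponseConfig:
    """Operational timings and level definitions (documented defaults).

    Printed plan anchors are fixed (SAR start 5 min, self-evacuation by
    3 min, fuselage holes at 21 min, FMP setup 8 min, initial dispatch
    5/4/2); the remaining durations and level tables stand in for the
    region-specific plan annexes and are freely configurable.
    """

    horizon: float = 720.0
    self_evac_minute: float = 3.0
    sar_start: float = 5.0
    hole_minute: float = 21.0
    hole_multiplier: float = 3.0  # one opening initially, two more at 21 min
    sar_rates: dict = field(  # non-ambulatory victims extracted per 10 min
        default_factory=lambda: {"low": 4.0, "medium": 8.0, "high": 16.0}
    )
    triage_duration: float = 1.0
    airport_staff_arrival: float = 4.0
    fmp_setup: float = 8.0
    treatment_delivery: dict = field(
        default_factory=lambda: {"T1": 12.0, "T2": 8.0, "T3": 5.0, "T4": 12.0}
    )
    enroute_delivery: float = 6.0
    loading_time: float = 2.0
    unloading_time: float = 1.0
    nuca_transfer: float = 2.0
    nuca_exam: float = 1.0
    nucf_bus_capacity: int = 8
    nucf_bus_headway: float = 20.0
    initial_ambulances: int = 5
    initial_mmts: int = 4  # including the commander
    initial_rits: int = 2
    pit_ambulance_every: int = 3  # every n-th rostered ambulance is a PIT unit
    resource_levels: dict = field(
        default_factory=lambda: {
            "low": {"ambulances": 12, "mmts": 5, "first_wave_mmts": 3, "reinforce_at": 25.0},
            "medium": {"ambulances": 19, "mmts": 7, "first_wave_mmts": 3, "reinforce_at": 20.0},
            "normal": {"ambulances": 28, "mmts": 10, "first_wave_mmts": 3, "reinforce_at": 15.0},
            "high": {"ambulances": 38, "mmts": 10, "first_wave_mmts": 7, "reinforce_at": 15.0},
        }
    )
    hcf_levels: dict = field(  # (initial surge, subsequent patients/hour)
        default_factory=lambda: {"low": (4, 2.0), "medium": (8, 4.0), "high": (12, 6.0)}
    )

    def __post_init__(self):
        if not (0 < self.horizon < 1000):
            raise ValueError(
                "horizon must be < 1000 min: the priority code reserves 3 digits "
                "for the arrival minute"
            )


@dataclass(frozen=True)
class DesignPoint:
    """One combination of the seven interventional factor levels."""

    policy: str = "stay_and_play"
    triage: bool = True
    sar: str = "medium"
    resources: str = "normal"
    supervision: str = "best_available"
    distribution: str = "nearest_first"
    hcf_capacity: str = "medium"
    design_id: str = ""

    def __post_init__(self):
        checks = [
            (self.policy, POLICIES),
            (self.sar, SAR_LEVELS),
            (self.resources, RESOURCE_LEVELS),
            (self.supervision, SUPERVISION_LEVELS),
            (self.distribution, DISTRIBUTIONS),
            (self.hcf_capacity, HCF_LEVELS),
        ]
        for value, allowed in checks:
            if value not in allowed:
                raise ValueError(f"{value!r} not in {allowed}")


# ---------------------------------------------------------------------------
# pure planning operations
# ---------------------------------------------------------------------------


def sar_process(n_nonambulatory: int, rate_level: str, seed: int, config=None):
    """Extraction schedule for the non-ambulatory victims.

    Returns ``(times, order)``: extraction clock times (minutes) and a seeded
    random permutation of ``range(n_nonambulatory)`` giving the extraction
    order.  Extraction starts at ``sar_start`` at the level's per-10-minute
    rate; the rate is multiplied by ``hole_multiplier`` from ``hole_minute``
    on (the two extra fuselage holes).
    """
    config = config or ResponseConfig()
    if rate_level not in SAR_LEVELS:
        raise ValueError(f"unknown SAR rate level {rate_level!r}")
    rate = config.sar_rates[rate_level] / 10.0  # victims per minute
    times = []
    t = config.sar_start
    for _ in range(n_nonambulatory):
        r = rate * (config.hole_multiplier if t >= config.hole_minute else 1.0)
        t = t + 1.0 / r
        # an interval straddling the hole opening finishes at the faster rate
        if t > config.hole_minute and (t - 1.0 / r) < config.hole_minute:
            before = config.hole_minute - (t - 1.0 / r)
            remaining = 1.0 - before * rate
            t = config.hole_minute + remaining / (rate * config.hole_multiplier)
        times.append(t)
    order = np.random.default_rng(seed).permutation(n_nonambulatory)
    return times, list(map(int, order))


def dispatch_plan(resource_level: str, geometry, roster, config=None) -> dict:
    """Timed dispatch of ambulances, MMTs and RITs for a resource level.

    The initial wave (5 ambulances from the nearest stations, 4 MMTs of
    which the first to arrive commands, 2 RITs) leaves at t=0; reinforcements
    up to the level's totals leave at the level's reinforcement time.  The
    high level sends 7 working MMTs in the first wave.
    """
    config = config or ResponseConfig()
    if resource_level not in RESOURCE_LEVELS:
        raise ValueError(f"unknown resource level {resource_level!r}")
    lvl = config.resource_levels[resource_level]

    # ambulances: nearest stations first, wrap around if more than stations
    stations = sorted(
        (geometry.travel_minutes(f"S{i:02d}", "CCP"), f"S{i:02d}")
        for i in range(1, roster.n_stations + 1)
    )
    ambulances = []
    for i in range(min(lvl["ambulances"], roster.n_ambulances)):
        tt, station = stations[i % len(stations)]
        depart = 0.0 if i < config.initial_ambulances else lvl["reinforce_at"]
        ambulances.append(
            {
                "id": f"A{i + 1:02d}",
                "station": station,
                "type": "PIT" if (i + 1) % config.pit_ambulance_every == 0 else "BLS",
                "depart": depart,
                "arrive": depart + tt,
            }
        )

    n_first = 1 + lvl["first_wave_mmts"]  # commander + working first wave
    mmts = []
    for i in range(min(lvl["mmts"], roster.n_mmts)):
        base = f"M{i + 1:02d}"
        tt = geometry.travel_minutes(base, "CCP", vehicle="mmt")
        depart = 0.0 if i < max(config.initial_mmts, n_first) else lvl["reinforce_at"]
        if resource_level != "high" and i >= config.initial_mmts:
            depart = lvl["reinforce_at"]
        if i == 0:
            role = "commander"
        elif i == 1:
            role = "triage"
        elif i in (2, 3):
            role = "fmp_setup"
        else:
            role = "treat"
        mmts.append(
            {"id": f"MMT{i + 1}", "base": base, "role": role,
             "depart": depart, "arrive": depart + tt}
        )

    rits = [
        {"id": f"RIT{i + 1}", "depart": 0.0, "arrive": 8.0 + 2.0 * i}
        for i in range(config.initial_rits)
    ]
    return {"ambulances": ambulances, "mmts": mmts, "rits": rits}


def supervision_assignment(victim, level: str, ambulance_type: str, idle_mmts: list):
    """Crew for an ambulance departure under a supervision level.

    Returns ``(crew, skill)`` where ``crew`` is an MMT drawn from
    ``idle_mmts`` (removed by the caller) or ``None``; returns ``None`` when
    the required crew is unavailable and the departure must wait.
    """
    if level not in SUPERVISION_LEVELS:
        raise ValueError(f"unknown supervision level {level!r}")
    if level == "emt":
        return (None, "EMT")
    if level == "nurse":
        if ambulance_type == "PIT":
            return (None, "PIT")
        return (idle_mmts[0], "MMT") if idle_mmts else None
    if level == "physician_nurse":
        return (idle_mmts[0], "MMT") if idle_mmts else None
    # best_available: highest idle skill, never wait
    if idle_mmts:
        return (idle_mmts[0], "MMT")
    return (None, "PIT" if ambulance_type == "PIT" else "EMT")


def distribute_to_hcf(victim, policy: str, hcfs: list):
    """Pick the destination hospital for an urgent victim.

    ``hcfs`` are :class:`HCFState` objects.  Nearest-first sends the victim
    to the closest capable hospital with uncommitted surge capacity, falling
    back to the closest capable one when every surge is committed (a queue
    then forms at admission).  Round-robin rotates among capable hospitals
    proportionally to their surge capacity.
    """
    if policy not in DISTRIBUTIONS:
        raise ValueError(f"unknown distribution policy {policy!r}")
    need = victim.profile.destination_need if hasattr(victim, "profile") else "general"
    capable = [h for h in hcfs if need == "general" or need in h.spec.capabilities]
    if not capable:
        return None
    if policy == "nearest_first":
        by_distance = sorted(capable, key=lambda h: (h.spec.distance_km, h.spec.hcf_id))
        for h in by_distance:
            if h.surge_remaining - h.inbound > 0:
                h.inbound += 1
                return h
        h = by_distance[0]
        h.inbound += 1
        return h
    # round-robin, weighted by initial surge capacity
    h = min(capable, key=lambda h: (h.assigned / h.weight, h.spec.distance_km, h.spec.hcf_id))
    h.assigned += 1
    h.inbound += 1
    return h


# ---------------------------------------------------------------------------
# runtime state containers
# ---------------------------------------------------------------------------


class PriorityQueue:
    """Victim queue ordered by (priority key, entry order, victim id)."""

    def __init__(self):
        self._heap: list = []
        self._members: set = set()
        self._seq = 0

    def __len__(self):
        return len(self._members)

    def __contains__(self, entity):
        return entity.victim_id in self._members

    def push(self, entity, code: int = 0):
        self._seq += 1
        heapq.heappush(self._heap, (code, self._seq, entity.victim_id, entity))
        self._members.add(entity.victim_id)

    def remove(self, entity):
        self._members.discard(entity.victim_id)

    def peek(self):
        while self._heap:
            code, seq, vid, entity = self._heap[0]
            if vid in self._members and entity.alive:
                return entity
            heapq.heappop(self._heap)
            self._members.discard(vid)
        return None

    def pop(self):
        entity = self.peek()
        if entity is not None:
            heapq.heappop(self._heap)
            self._members.discard(entity.victim_id)
        return entity


@dataclass
class Provider:
    provider_id: str
    skill: str
    role: str
    location: str = "en_route"
    busy: bool = False
    present: bool = False


@dataclass
class AmbulanceUnit:
    amb_id: str
    amb_type: str
    station: str
    location: str = "en_route"
    state: str = "to_scene"  # idle | loading | to_HCF | returning | to_scene
    assigned: object = None
    crew: object = None
    present: bool = False


@dataclass
class HCFState:
    spec: object
    surge_remaining: int
    rate_per_hour: float
    next_slot: float = 0.0
    admitted: int = 0
    inbound: int = 0
    assigned: int = 0
    weight: int = 1


@dataclass
class RunRecord:
    """Per-run results: terminal dispositions and audit timestamps."""

    design: DesignPoint
    seed: int
    injured_total: int
    total_deaths: int
    deaths_by_location: dict
    admitted: int
    admissions_per_hcf: dict
    discharged: int
    in_system: int
    timestamps: dict
    event_log: EventLog = dataclasses.field(repr=False, default=None)


# ---------------------------------------------------------------------------
# the simulation
# ---------------------------------------------------------------------------


class Simulation:
    """One simulated response to the scenario under one design point."""

    def __init__(self, scenario: Scenario, design: DesignPoint | None = None,
                 seed: int = 0, config: ResponseConfig | None = None):
        self.scenario = scenario
        self.design = design or DesignPoint()
        self.seed = seed
        self.config = config or ResponseConfig()
        self.log = EventLog()
        self.sched = Scheduler(self.log)
        self.monitor = ClinicalMonitor(
            self.sched, on_condition_change=self._on_condition_change
        )
        self.timestamps: dict = {}

    # -- setup ---------------------------------------------------------------
    def _setup(self):
        cfg, design = self.config, self.design
        self.entities = [VictimEntity(p) for p in self.scenario.victims]
        self.by_id = {e.victim_id: e for e in self.entities}
        for e in self.entities:
            self.monitor.register(e)
            e.logistics.on_death = self._victim_died
            e.service = None  # (kind, resource, handle) while being served

        surge, rate = cfg.hcf_levels[design.hcf_capacity]
        self.hcfs = [
            HCFState(spec=h, surge_remaining=surge, rate_per_hour=rate, weight=surge)
            for h in self.scenario.roster.hcfs
        ]

        plan = dispatch_plan(design.resources, self.scenario.geometry,
                             self.scenario.roster, cfg)
        self.plan = plan
        self.ambulances = []
        for a in plan["ambulances"]:
            unit = AmbulanceUnit(a["id"], a["type"], a["station"])
            self.ambulances.append(unit)
            self.sched.schedule(a["arrive"], "vehicle_arrival", a["id"],
                                lambda u=unit: self._ambulance_arrives(u),
                                unit="ambulance", station=a["station"])
        self.mmts = []
        for m in plan["mmts"]:
            prov = Provider(m["id"], "MMT", m["role"])
            self.mmts.append(prov)
            self.sched.schedule(m["arrive"], "vehicle_arrival", m["id"],
                                lambda p=prov: self._mmt_arrives(p),
                                unit="mmt", role=m["role"])
        self.rits = []
        for r in plan["rits"]:
            prov = Provider(r["id"], "RIT", "nuca")
            self.rits.append(prov)
            self.sched.schedule(r["arrive"], "vehicle_arrival", r["id"],
                                lambda p=prov: self._rit_arrives(p), unit="rit")

        setup_arrivals = [m["arrive"] for m in plan["mmts"] if m["role"] == "fmp_setup"]
        self.timestamps["fmp_team_arrival"] = max(setup_arrivals) if setup_arrivals else None
        self.fmp_ready = (
            max(setup_arrivals) + cfg.fmp_setup if setup_arrivals else math.inf
        )
        if design.policy == "stay_and_play" and math.isfinite(self.fmp_ready):
            self.sched.schedule(self.fmp_ready, "dispatch_wave", "FMP",
                                self._fmp_operational, note="fmp_operational")
        self.timestamps["fmp_ready"] = self.fmp_ready
        self.timestamps["initial_dispatch"] = {
            "ambulances": sum(1 for a in plan["ambulances"] if a["depart"] == 0.0),
            "mmts": sum(1 for m in plan["mmts"] if m["depart"] == 0.0),
            "rits": len(plan["rits"]),
        }

        # queues
        self.ccp_triage_queue = PriorityQueue()
        self.ccp_evac = PriorityQueue()
        self.fmp_treatment = PriorityQueue()
        self.fmp_evac = PriorityQueue()
        self.nuca_exam_queue = PriorityQueue()
        self.nuca_waiting_bus: list = []
        self.bus_idle = True
        self.bus_timer = None
        self.triage_officers = []  # (Provider, present_from)
        airport = Provider("AIRPORT-MED", "PIT", "triage")
        self.triage_officers.append(airport)
        self.sched.schedule(cfg.airport_staff_arrival, "vehicle_arrival",
                            airport.provider_id,
                            lambda p=airport: self._officer_arrives(p), unit="triage")

        # victim arrivals
        nonamb = [e for e in self.entities if not e.profile.ambulatory]
        amb = [e for e in self.entities if e.profile.ambulatory]
        self.n_to_extract = len(nonamb)
        self.n_extracted = 0
        for e in amb:
            self.sched.schedule(cfg.self_evac_minute, "vehicle_arrival", e.victim_id,
                                lambda v=e: self._ccp_arrival(v), note="self_evacuated")
        times, order = sar_process(len(nonamb), design.sar, self.seed, cfg)
        for t, idx in zip(times, order):
            e = nonamb[idx]
            self.sched.schedule(t, "sar_extraction", e.victim_id,
                                lambda v=e: self._extracted(v))

    # -- arrivals ------------------------------------------------------------
    def _ambulance_arrives(self, unit: AmbulanceUnit):
        unit.present = True
        unit.state = "idle"
        if self.design.policy == "stay_and_play" and not self._ccp_shuttle_needed():
            unit.location = "FMP"
            self._match_fmp()
        else:
            unit.location = "CCP"
            self._match_ccp()

    def _mmt_arrives(self, prov: Provider):
        prov.present = True
        if prov.role == "commander":
            prov.location = "CCP"  # commands only; never treats or transports
            return
        if prov.role == "triage":
            prov.location = "CCP"
            self.triage_officers.append(prov)
            self._match_triage()
            return
        if self.design.policy == "stay_and_play":
            prov.location = "FMP"
            if prov.role == "fmp_setup" and self.sched.now >= self.fmp_ready - 1e-9:
                prov.role = "treat"  # setup finished before this MMT returned
            self._match_fmp()
        else:
            prov.role = "treat"  # transport supervision pool at the CCP
            prov.location = "CCP"
            self._match_ccp()

    def _rit_arrives(self, prov: Provider):
        prov.present = True
        prov.location = "NUCA"
        self._match_nuca()

    def _officer_arrives(self, prov: Provider):
        prov.present = True
        prov.location = "CCP"
        self._match_triage()

    def _extracted(self, e: VictimEntity):
        self.n_extracted += 1
        if e.alive and e.disposition is None:
            self._ccp_arrival(e)
        else:
            self._match_ccp()  # extraction done may release the shuttle pool

    def _ccp_arrival(self, e: VictimEntity):
        if not e.alive or e.disposition is not None:
            return
        e.location = "CCP"
        e.arrival_minute = self.sched.now
        if e.profile.ambulatory:  # preliminary sorting: non-urgent
            self.sched.schedule(self.sched.now + self.config.nuca_transfer,
                                "vehicle_arrival", e.victim_id,
                                lambda v=e: self._nuca_arrival(v), note="to_nuca")
            return
        if self.design.triage:
            self.ccp_triage_queue.push(e)
            self._match_triage()
        else:
            self.ccp_evac.push(e, code=0)  # first-in-first-out
            self._match_ccp()

    # -- triage ---------------------------------------------------------------
    def _match_triage(self):
        if not self.design.triage:
            return
        for officer in self.triage_officers:
            if not officer.present or officer.busy:
                continue
            victim = self.ccp_triage_queue.pop()
            if victim is None:
                break
            officer.busy = True
            h = self.sched.schedule(
                self.sched.now + self.config.triage_duration, "triage_complete",
                victim.victim_id,
                lambda v=victim, o=officer: self._triage_done(v, o),
            )
            victim.service = ("triage", officer, h)
        self._maybe_release_triage_mmt()

    def _triage_done(self, victim: VictimEntity, officer: Provider):
        officer.busy = False
        victim.service = None
        if victim.alive:
            cc = victim.current_condition()
            cat = int(cc.triage_category[1])
            code = priority_code(cat, cc.rpm, int(victim.arrival_minute))
            victim.priority_key = code
            self.ccp_evac.push(victim, code=code)
        self._match_triage()
        self._match_ccp()

    def _maybe_release_triage_mmt(self):
        """Primary triage finished: the triage MMT moves on to the FMP."""
        if self.n_extracted < self.n_to_extract or len(self.ccp_triage_queue):
            return
        if any(o.busy for o in self.triage_officers):
            return
        for prov in self.mmts:
            if prov.role == "triage" and prov.present and prov.location == "CCP":
                if prov in self.triage_officers:
                    self.triage_officers.remove(prov)
                if self.design.policy == "stay_and_play":
                    prov.present = False
                    prov.role = "treat"
                    self.sched.schedule(
                        self.sched.now + self.scenario.geometry.travel_minutes("CCP", "FMP"),
                        "vehicle_arrival", prov.provider_id,
                        lambda p=prov: self._mmt_arrives(p), unit="mmt", role="treat")
                else:
                    prov.role = "treat"  # joins the CCP supervision pool
                    self._match_ccp()

    # -- CCP evacuation -------------------------------------------------------
    def _ccp_shuttle_needed(self) -> bool:
        if self.design.policy != "stay_and_play":
            return False
        return (self.n_extracted < self.n_to_extract
                or len(self.ccp_evac) > 0
                or len(self.ccp_triage_queue) > 0)

    def _idle_mmts(self, location: str) -> list:
        return [p for p in self.mmts
                if p.present and not p.busy and p.location == location
                and p.role == "treat"]

    def _match_ccp(self):
        cfg, design = self.config, self.design
        idle = [a for a in self.ambulances
                if a.present and a.state == "idle" and a.location == "CCP"]
        if design.policy == "stay_and_play":
            for unit in idle:
                victim = self.ccp_evac.pop()
                if victim is None:
                    break
                self._start_transport(unit, victim, dest="FMP", crew=None, skill=None)
            # shuttle work finished: relocate idle CCP ambulances to the FMP
            if not self._ccp_shuttle_needed():
                for unit in idle:
                    if unit.state == "idle" and unit.location == "CCP":
                        self._relocate_ambulance(unit, "FMP")
            return
        # scoop-and-run: direct evacuation CCP -> HCF with en-route care
        for unit in idle:
            victim = self.ccp_evac.peek()
            if victim is None:
                break
            crew_skill = supervision_assignment(
                victim, design.supervision, unit.amb_type, self._idle_mmts("CCP"))
            if crew_skill is None:
                break  # required crew unavailable: departure waits
            self.ccp_evac.pop()
            crew, skill = crew_skill
            hcf = distribute_to_hcf(victim, design.distribution, self.hcfs)
            self._start_transport(unit, victim, dest=hcf, crew=crew, skill=skill)

    def _relocate_ambulance(self, unit: AmbulanceUnit, dest: str):
        unit.state = "returning"
        unit.present = False
        tt = self.scenario.geometry.travel_minutes(unit.location, dest)
        unit.location = dest
        self.sched.schedule(self.sched.now + tt, "vehicle_arrival", unit.amb_id,
                            lambda u=unit: self._ambulance_back(u, dest),
                            unit="ambulance", note=f"relocate_{dest}")

    # -- FMP ------------------------------------------------------------------
    def _fmp_arrival(self, e: VictimEntity):
        if not e.alive:
            return
        e.location = "FMP"
        self.fmp_treatment.push(e, code=e.priority_key or 0)
        self._match_fmp()

    def _fmp_operational(self):
        """FMP setup complete: the setup MMTs become treatment providers."""
        for prov in self.mmts:
            if prov.role == "fmp_setup" and prov.present and prov.location == "FMP":
                prov.role = "treat"
        self._match_fmp()

    def _match_fmp(self):
        if self.design.policy != "stay_and_play":
            return
        cfg = self.config
        # treatment: idle qualified providers to lowest-code waiting victims
        if self.sched.now >= self.fmp_ready - 1e-9:
            for prov in self._idle_mmts("FMP"):
                victim = self.fmp_treatment.pop()
                if victim is None:
                    break
                prov.busy = True
                start = self.sched.now
                if "first_fmp_treatment_start" not in self.timestamps:
                    self.timestamps["first_fmp_treatment_start"] = start
                delivery = cfg.treatment_delivery[victim.current_condition().triage_category]
                h = self.sched.schedule(
                    start + delivery, "treatment_complete", victim.victim_id,
                    lambda v=victim, p=prov: self._fmp_treated(v, p),
                    skill="MMT", start=f"{start:.3f}", point="FMP")
                victim.service = ("treatment", prov, h)
        # evacuation: idle ambulances + supervision crew to treated victims
        idle = [a for a in self.ambulances
                if a.present and a.state == "idle" and a.location == "FMP"]
        for unit in idle:
            victim = self.fmp_evac.peek()
            if victim is None:
                break
            crew_skill = supervision_assignment(
                victim, self.design.supervision, unit.amb_type, self._idle_mmts("FMP"))
            if crew_skill is None:
                break  # victims may die while waiting for such a team
            self.fmp_evac.pop()
            crew, skill = crew_skill
            hcf = distribute_to_hcf(victim, self.design.distribution, self.hcfs)
            self._start_transport(unit, victim, dest=hcf, crew=crew, skill=skill)

    def _fmp_treated(self, victim: VictimEntity, prov: Provider):
        prov.busy = False
        victim.service = None
        if victim.alive:
            victim.logistics.complete_treatment("MMT")
            # loading may only start after the delivery time has expired
            self.fmp_evac.push(victim, code=victim.priority_key or 0)
        self._match_fmp()

    # -- transport ------------------------------------------------------------
    def _start_transport(self, unit, victim, dest, crew, skill):
        """Assign pickup (immutable thereafter), load, depart, travel."""
        unit.state = "loading"
        unit.assigned = victim
        unit.crew = crew
        if crew is not None:
            crew.busy = True
        victim.service = None
        h = self.sched.schedule(
            self.sched.now + self.config.loading_time, "loading_complete",
            victim.victim_id,
            lambda: self._depart(unit, victim, dest, crew, skill),
            ambulance=unit.amb_id)
        victim.service = ("loading", unit, h)

    def _depart(self, unit, victim, dest, crew, skill):
        victim.service = None
        geometry = self.scenario.geometry
        origin = unit.location
        dest_name = dest if isinstance(dest, str) else dest.spec.hcf_id
        tt = geometry.travel_minutes(origin, dest_name)
        self.sched.log.record(self.sched.now, "vehicle_departure", unit.amb_id,
                              victim=victim.victim_id, dest=dest_name,
                              crew=getattr(crew, "provider_id", "none"))
        unit.state = "to_HCF" if not isinstance(dest, str) else "to_FMP"
        victim.location = "ambulance"
        if skill is not None and victim.alive:
            # care en route: treatment delivered by the supervising crew
            self.sched.schedule(
                self.sched.now + self.config.enroute_delivery, "treatment_complete",
                victim.victim_id,
                lambda v=victim, s=skill: (
                    v.logistics.complete_treatment(s) if v.alive and v.disposition != "admitted" else None
                ),
                skill=skill, point="ambulance")
        self.sched.schedule(
            self.sched.now + tt, "vehicle_arrival", unit.amb_id,
            lambda: self._transport_arrived(unit, victim, dest, crew, origin),
            dest=dest_name, victim=victim.victim_id)

    def _transport_arrived(self, unit, victim, dest, crew, origin):
        if isinstance(dest, str):  # CCP -> FMP shuttle leg
            unit.location = "FMP"
            if victim.alive:
                self.sched.schedule(
                    self.sched.now + self.config.unloading_time, "vehicle_arrival",
                    victim.victim_id, lambda v=victim: self._fmp_arrival(v),
                    note="unloaded_fmp")
            unit.assigned = None
            if self._ccp_shuttle_needed():
                self._relocate_ambulance(unit, "CCP")
            else:
                unit.state = "idle"
                self._match_fmp()
            return
        hcf = dest
        unit.location = hcf.spec.hcf_id
        hcf.inbound -= 1
        if victim.alive:
            victim.location = hcf.spec.hcf_id
            self.sched.schedule(
                self.sched.now + self.config.unloading_time, "vehicle_arrival",
                victim.victim_id, lambda: self._hcf_admission(hcf, victim),
                note="unloaded_hcf", hcf=hcf.spec.hcf_id)
        unit.assigned = None
        # return to the staging point and rejoin the pool
        back = origin
        if back == "CCP" and self.design.policy == "stay_and_play":
            back = "FMP" if not self._ccp_shuttle_needed() else "CCP"
        unit.state = "returning"
        tt = self.scenario.geometry.travel_minutes(unit.location, back)
        self.sched.schedule(self.sched.now + tt, "vehicle_arrival", unit.amb_id,
                            lambda: self._ambulance_back(unit, back, crew),
                            unit="ambulance", note="returned")

    def _ambulance_back(self, unit, point, crew=None):
        unit.location = point
        unit.state = "idle"
        unit.present = True
        if crew is not None:
            crew.busy = False
            crew.location = point
        if point == "CCP":
            self._match_ccp()
        else:
            self._match_fmp()

    # -- hospital admission ----------------------------------------------------
    def _hcf_admission(self, hcf: HCFState, victim: VictimEntity):
        if not victim.alive:
            return
        victim.location = hcf.spec.hcf_id
        if hcf.surge_remaining > 0:
            hcf.surge_remaining -= 1
            hcf.next_slot = max(hcf.next_slot,
                                self.sched.now + 60.0 / hcf.rate_per_hour)
            self._admit(hcf, victim, self.sched.now, immediate=True)
        else:
            t = max(self.sched.now, hcf.next_slot)
            hcf.next_slot = t + 60.0 / hcf.rate_per_hour
            self.sched.schedule(t, "admission", victim.victim_id,
                                lambda: self._admit(hcf, victim, self.sched.now),
                                hcf=hcf.spec.hcf_id, queued="yes")

    def _admit(self, hcf, victim, when, immediate=False):
        if not victim.alive:
            return  # died while awaiting admission
        if immediate:
            self.sched.log.record(self.sched.now, "admission", victim.victim_id,
                                  hcf=hcf.spec.hcf_id, queued="no")
        victim.disposition = "admitted"
        hcf.admitted += 1
        self.monitor_stop(victim)

    def monitor_stop(self, victim):
        h = self.monitor._pending.pop(victim.victim_id, None)
        if h is not None and not h.fired and not h.cancelled:
            self.sched.cancel(h)

    # -- NUCA -------------------------------------------------------------------
    def _nuca_arrival(self, e: VictimEntity):
        if not e.alive or e.disposition is not None:
            return
        e.location = "NUCA"
        self.nuca_exam_queue.push(e)
        self._match_nuca()

    def _match_nuca(self):
        for prov in self.rits:
            if not prov.present or prov.busy:
                continue
            victim = self.nuca_exam_queue.pop()
            if victim is None:
                break
            prov.busy = True
            h = self.sched.schedule(
                self.sched.now + self.config.nuca_exam, "triage_complete",
                victim.victim_id,
                lambda v=victim, p=prov: self._nuca_examined(v, p), point="NUCA")
            victim.service = ("nuca_exam", prov, h)

    def _nuca_examined(self, victim, prov):
        prov.busy = False
        victim.service = None
        if victim.alive and victim.location == "NUCA":
            self.nuca_waiting_bus.append(victim)
            self._check_bus()
        self._match_nuca()

    def _check_bus(self):
        cfg = self.config
        if not self.bus_idle or not self.nuca_waiting_bus:
            return
        if len(self.nuca_waiting_bus) >= cfg.nucf_bus_capacity:
            self._bus_depart()
        elif self.bus_timer is None:
            self.bus_timer = self.sched.schedule(
                self.sched.now + cfg.nucf_bus_headway, "vehicle_departure", "NUCF-BUS",
                lambda: self._bus_depart(), note="headway")

    def _bus_depart(self):
        if not self.bus_idle:
            return
        if self.bus_timer is not None:
            if not self.bus_timer.fired and not self.bus_timer.cancelled:
                self.sched.cancel(self.bus_timer)
            self.bus_timer = None
        riders = [v for v in self.nuca_waiting_bus[: self.config.nucf_bus_capacity]
                  if v.alive and v.location == "NUCA"]
        self.nuca_waiting_bus = self.nuca_waiting_bus[self.config.nucf_bus_capacity:]
        if not riders:
            self._check_bus()
            return
        self.bus_idle = False
        tt = self.scenario.geometry.travel_minutes("NUCA", "NUCF", vehicle="bus")
        self.sched.schedule(self.sched.now + tt, "vehicle_arrival", "NUCF-BUS",
                            lambda: self._bus_arrived(riders), n=len(riders))

    def _bus_arrived(self, riders):
        for v in riders:
            if v.alive:
                v.location = "NUCF"
                v.disposition = "discharged"
                self.monitor_stop(v)
        tt = self.scenario.geometry.travel_minutes("NUCF", "NUCA", vehicle="bus")
        self.sched.schedule(self.sched.now + tt, "vehicle_arrival", "NUCF-BUS",
                            lambda: self._bus_back(), note="returned")

    def _bus_back(self):
        self.bus_idle = True
        self._check_bus()

    # -- clinical callbacks ------------------------------------------------------
    def _on_condition_change(self, entity: VictimEntity):
        """NUCA re-examination: deteriorated walking wounded go to the FMP."""
        if entity.location != "NUCA" or entity.disposition is not None:
            return
        cat = entity.current_condition().triage_category
        if cat not in ("T1", "T2"):
            return
        self.nuca_exam_queue.remove(entity)
        self.nuca_waiting_bus = [v for v in self.nuca_waiting_bus if v is not entity]
        entity.arrival_minute = self.sched.now
        cc = entity.current_condition()
        if self.design.triage:
            entity.priority_key = priority_code(
                int(cat[1]), cc.rpm, int(self.sched.now))
        if self.design.policy == "stay_and_play":
            self.sched.schedule(
                self.sched.now + self.config.nuca_transfer, "vehicle_arrival",
                entity.victim_id, lambda v=entity: self._fmp_arrival(v),
                note="nuca_transfer")
        else:
            entity.location = "CCP"
            self.ccp_evac.push(entity, code=entity.priority_key or 0)
            self._match_ccp()

    def _victim_died(self, entity: VictimEntity):
        """Death: withdraw from all queues, release resources."""
        for q in (self.ccp_triage_queue, self.ccp_evac, self.fmp_treatment,
                  self.fmp_evac, self.nuca_exam_queue):
            q.remove(entity)
        self.nuca_waiting_bus = [v for v in self.nuca_waiting_bus if v is not entity]
        service = getattr(entity, "service", None)
        entity.service = None
        if service is None:
            return
        kind, resource, handle = service
        if not handle.fired and not handle.cancelled:
            self.sched.cancel(handle)
        if kind in ("triage", "treatment", "nuca_exam"):
            resource.busy = False
        elif kind == "loading":
            unit = resource
            crew = unit.crew
            unit.assigned = None
            unit.crew = None
            unit.state = "idle"
            if crew is not None:
                crew.busy = False
        if kind == "treatment" or kind == "loading":
            self._match_fmp()
            self._match_ccp()
        elif kind in ("triage",):
            self._match_triage()
        elif kind == "nuca_exam":
            self._match_nuca()

    # -- run -----------------------------------------------------------------
    def run(self) -> RunRecord:
        self._setup()
        self.sched.run_until(self.config.horizon)
        deaths_by_location: dict = {}
        dead = admitted = discharged = 0
        for e in self.entities:
            if e.disposition == "dead":
                dead += 1
                loc = e.death_location or "site"
                zone = ("scene" if loc in ("site", "CCP", "NUCA") else
                        "FMP" if loc == "FMP" else
                        "transport" if loc == "ambulance" else
                        "awaiting_admission")
                deaths_by_location[zone] = deaths_by_location.get(zone, 0) + 1
            elif e.disposition == "admitted":
                admitted += 1
            elif e.disposition == "discharged":
                discharged += 1
        injured = len(self.entities)
        in_system = injured - dead - admitted - discharged
        return RunRecord(
            design=self.design,
            seed=self.seed,
            injured_total=injured,
            total_deaths=dead,
            deaths_by_location=deaths_by_location,
            admitted=admitted,
            admissions_per_hcf={h.spec.hcf_id: h.admitted for h in self.hcfs},
            discharged=discharged,
            in_system=in_system,
            timestamps=self.timestamps,
            event_log=self.log,
        )


def run_default(design: DesignPoint | None = None, seed: int = 0,
                scenario: Scenario | None = None,
                config: ResponseConfig | None = None) -> RunRecord:
    """Run the default airport scenario under one design point."""
    from .scenario import build_scenario

    scenario = scenario or build_scenario(seed=seed)
    return Simulation(scenario, design=design, seed=seed, config=config).run()
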