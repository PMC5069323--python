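"""Victim creation model and default scenario fixtures.

Builds the incident scenario: the casualty census, the victim profile
library, the mapping of profiles onto individual victims, attribute
assignment (ambulatory status, destination need) and the duplication of each
victim entity into a clinical facet (driving the monitoring model) and a
logistics facet (driving the response model) over shared state.

The default fixtures emulate an airliner crash at an international airport:
250 occupants, 205 injured (26 T1, 62 T2, 113 T3, 4 T4), 5 immediate
fatalities and 40 uninjured.  Victim profile parameters (initial RPM scores,
deterioration and treatment-effect timings) are documented defaults; dead
states are placed deterministically at the first 30-minute bin where the
victim's current-RPM survival probability reaches zero.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .tables import MOTOR_LEVELS, RPM_MAX, DeteriorationTable
from .victim import (
    ClinicalCondition,
    Transition,
    VictimProfile,
    VitalSigns,
)

# representative raw vitals for each coded value
_RR_FOR_CODE = {0: 0, 1: 5, 2: 40, 3: 30, 4: 16}
_PR_FOR_CODE = {0: 0, 1: 30, 2: 50, 3: 130, 4: 80}


@dataclass(frozen=True)
class Census:
    t1: int = 26
    t2: int = 62
    t3: int = 113
    t4: int = 4
    immediate_fatalities: int = 5
    uninjured: int = 40

    def __post_init__(self):
        if any(v < 0 for v in dataclasses.astuple(self)):
            raise ValueError("census counts must be non-negative")

    @property
    def injured(self) -> int:
        return self.t1 + self.t2 + self.t3 + self.t4

    @property
    def occupants(self) -> int:
        return self.injured + self.immediate_fatalities + self.uninjured

    def count(self, category: str) -> int:
        return getattr(self, category.lower())


def generate_census(config: dict | None = None) -> Census:
    """Return the configured census; default is the airport case study."""
    if config is None:
        return Census()
    census = Census(**config)
    if "occupants" in (config or {}):
        raise ValueError("occupants is derived, not configurable")
    return census


# ---------------------------------------------------------------------------
# profile library generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileParams:
    """Per-category clinical trajectory parameters (documented defaults).

    ``initial_rpm`` lists one starting RPM per profile variant; ``drop`` is
    the RPM lost per 30-min bin on the untreated pathway.  Treatment-effect
    delays are the minutes between treatment delivery and the state change.
    """

    initial_rpm: dict = field(
        default_factory=lambda: {
            "T1": (4, 5, 6),
            "T2": (8, 9, 10),
            "T3": (11, 12, 12),
            "T4": (1, 2, 1),
        }
    )
    drop_per_bin: dict = field(
        default_factory=lambda: {"T1": 1.0, "T2": 0.5, "T3": 0.0, "T4": 1.0}
    )
    bin_minutes: float = 30.0
    t3_stabilize_dwell: float = 30.0
    mmt_rpm_gain: int = 2
    pit_rpm_gain: int = 1
    effect_emt: float = 5.0
    effect_pit: float = 8.0
    effect_mmt: float = 10.0
    effect_ed: float = 5.0
    mmt_stabilize_dwell: float = 30.0
    pit_hold_dwell: float = 180.0
    emt_dwell_factor: float = 2.0  # EMT care halves the deterioration rate
    variants_per_category: int = 3


def _vitals_for_rpm(rpm: int, rng=None) -> VitalSigns:
    """A VitalSigns triple whose coded sum equals ``rpm``."""
    decompositions = [
        (m, p, rpm - m - p)
        for m in range(min(4, rpm) + 1)
        for p in range(min(4, rpm - m) + 1)
        if 0 <= rpm - m - p <= 4
    ]
    m, p, r = decompositions[-1] if rng is None else decompositions[
        int(rng.integers(len(decompositions)))
    ]
    return VitalSigns(
        respiratory_rate=_RR_FOR_CODE[r],
        pulse_rate=_PR_FOR_CODE[p],
        motor_response=MOTOR_LEVELS[m],
    )


def category_for_rpm(rpm: int, base: str) -> str:
    """Triage category of a condition, given the victim's base category."""
    if base == "T4":
        return "T4"
    if rpm >= 11:
        return base if base == "T3" else "T2" if base == "T2" else "T1"
    if rpm >= 8:
        return "T2" if base in ("T2", "T3") else "T1"
    return "T1"


def _build_profile(pid, category, r0, params: ProfileParams, table, rng) -> VictimProfile:
    conds: dict[str, ClinicalCondition] = {}
    trans: list[Transition] = []
    step = params.bin_minutes
    drop = params.drop_per_bin[category]

    def add_cond(cid, rpm, end_kind="none"):
        conds[cid] = ClinicalCondition.from_vitals(
            cid,
            _vitals_for_rpm(rpm, rng) if end_kind == "none" else _vitals_for_rpm(rpm),
            category_for_rpm(rpm, category),
            end_kind=end_kind,
        )
        return cid

    def add_dead(cid):
        conds[cid] = ClinicalCondition.from_vitals(
            cid, VitalSigns(0, 0, "none"), category, end_kind="dead"
        )
        return cid

    def stabilized(cid, rpm):
        conds[cid] = ClinicalCondition.from_vitals(
            cid, _vitals_for_rpm(rpm), category_for_rpm(rpm, category), end_kind="stabilized"
        )
        return cid

    def attach_mmt(src, src_rpm):
        """MMT treatment branch: improve RPM, then stabilize."""
        mid = f"{src}.mmt"
        rpm_new = min(RPM_MAX, src_rpm + params.mmt_rpm_gain)
        add_cond(mid, rpm_new)
        trans.append(Transition(src, mid, "treatment", params.effect_mmt, "MMT"))
        sid = stabilized(f"{mid}.stab", rpm_new)
        trans.append(Transition(mid, sid, "time", params.mmt_stabilize_dwell))
        # in-hospital care always stabilizes
        eid = stabilized(f"{src}.ed", min(RPM_MAX, src_rpm + params.mmt_rpm_gain))
        trans.append(Transition(src, eid, "treatment", params.effect_ed, "ED"))
        trans.append(Transition(mid, f"{mid}.stab", "treatment", params.effect_ed, "ED"))
        return mid

    def attach_pit(src, src_rpm):
        """Nurse/paramedic branch: small improvement, long hold, stabilize."""
        pid_ = f"{src}.pit"
        rpm_new = min(RPM_MAX, src_rpm + params.pit_rpm_gain)
        add_cond(pid_, rpm_new)
        trans.append(Transition(src, pid_, "treatment", params.effect_pit, "PIT"))
        sid = stabilized(f"{pid_}.stab", rpm_new)
        trans.append(Transition(pid_, sid, "time", params.pit_hold_dwell))
        attach_mmt(pid_, rpm_new)
        return pid_

    def attach_emt(src, src_rpm):
        """Basic care: hold current RPM, deteriorate at half rate thereafter."""
        prev, prev_rpm = src, src_rpm
        first = None
        for j, rpm in enumerate(range(src_rpm, -1, -1)):
            cid = f"{src}.emt{j}"
            add_cond(cid, rpm)
            if j == 0:
                trans.append(Transition(src, cid, "treatment", params.effect_emt, "EMT"))
                first = cid
            else:
                trans.append(
                    Transition(prev, cid, "time", params.emt_dwell_factor * step)
                )
            attach_mmt(cid, rpm)
            prev = cid
        did = add_dead(f"{src}.emt_dead")
        trans.append(Transition(prev, did, "time", params.emt_dwell_factor * step))
        return first

    # --- untreated (CCt) chain --------------------------------------------
    if drop == 0.0:
        c0 = add_cond("t0", r0)
        sid = stabilized("t0.stab", r0)
        trans.append(Transition(c0, sid, "time", params.t3_stabilize_dwell))
        attach_mmt(c0, r0)
    else:
        k = 0
        chain = []
        while True:
            rpm_k = max(0, r0 - int(np.floor(drop * k)))
            if table.lookup(rpm_k, step * k) == 0:
                break  # dead-state entry at this bin
            chain.append((f"t{k}", rpm_k))
            k += 1
        for cid, rpm in chain:
            add_cond(cid, rpm)
        did = add_dead("dead")
        for i, (cid, rpm) in enumerate(chain):
            target = chain[i + 1][0] if i + 1 < len(chain) else did
            trans.append(Transition(cid, target, "time", step))
            attach_mmt(cid, rpm)
            attach_pit(cid, rpm)
            attach_emt(cid, rpm)

    prof = VictimProfile(
        victim_id=pid,
        triage_mix_category=category,
        ambulatory=category == "T3",
        destination_need="general",
        initial_condition="t0",
        conditions=conds,
        transitions=trans,
    )
    prof.validate()
    return prof


def build_default_profiles(
    params: ProfileParams | None = None,
    table: DeteriorationTable | None = None,
    seed: int = 0,
) -> dict[str, VictimProfile]:
    """Generate the default profile library (variants A, B, C per category)."""
    params = params or ProfileParams()
    table = table or DeteriorationTable.default()
    rng = np.random.default_rng(seed)
    library: dict[str, VictimProfile] = {}
    for category in ("T1", "T2", "T3", "T4"):
        rpms = params.initial_rpm[category][: params.variants_per_category]
        for letter, r0 in zip("ABCDEFGH", rpms):
            pid = f"{category}-{letter}"
            library[pid] = _build_profile(pid, category, r0, params, table, rng)
    return library


# ---------------------------------------------------------------------------
# mapping and attributes
# ---------------------------------------------------------------------------


def map_profiles(census: Census, library: dict, seed: int) -> list[VictimProfile]:
    """Assign one profile of the matching category to every injured victim."""
    pools = {c: sorted(p for p, prof in library.items() if prof.triage_mix_category == c)
             for c in ("T1", "T2", "T3", "T4")}
    rng = np.random.default_rng(seed)
    victims: list[VictimProfile] = []
    n = 0
    for category in ("T1", "T2", "T3", "T4"):
        count = census.count(category)
        if count and not pools[category]:
            raise ValueError(f"profile library has no {category} profiles")
        for _ in range(count):
            n += 1
            pid = pools[category][int(rng.integers(len(pools[category])))]
            src = library[pid]
            victims.append(dataclasses.replace(src, victim_id=f"V{n:03d}"))
    return victims


def assign_attributes(victims, config: dict | None, seed: int):
    """Set ambulatory status and destination need on mapped victims.

    T3 victims (the walking wounded) are ambulatory; T1/T2/T4 are not.
    Destination needs are drawn per configured per-category fractions
    (default: everyone needs a general hospital).
    """
    config = config or {}
    fractions = config.get("destination_fractions", {})
    rng = np.random.default_rng(seed)
    out = []
    for v in victims:
        cat = v.triage_mix_category
        fr = fractions.get(cat, {})
        if any(not (0 <= x <= 1) for x in fr.values()) or sum(fr.values()) > 1 + 1e-9:
            raise ValueError(f"destination fractions for {cat} outside [0, 1]")
        u = float(rng.random())
        dest, acc = "general", 0.0
        for name in ("trauma_centre", "burn_centre"):
            acc += fr.get(name, 0.0)
            if u < acc:
                dest = name
                break
        out.append(
            dataclasses.replace(v, ambulatory=(cat == "T3"), destination_need=dest)
        )
    return out


# ---------------------------------------------------------------------------
# runtime entity with clinical / logistics facets
# ---------------------------------------------------------------------------


class ClinicalFacet:
    """Handle used by the victim monitoring model."""

    def __init__(self, entity):
        self.entity = entity
        self.on_treatment = None  # set by the monitor
        self.treatment_triggers: list = []

    def notify_death(self, time) -> None:
        self.entity._propagate_death(time)


class LogisticsFacet:
    """Handle used by the medical response model."""

    def __init__(self, entity):
        self.entity = entity
        self.on_death = None  # set by the response model
        self.death_notifications: list = []

    def complete_treatment(self, skill) -> None:
        self.entity._propagate_treatment(skill)


class VictimEntity:
    """One victim's shared runtime state, seen through two facets."""

    def __init__(self, profile: VictimProfile):
        self.profile = profile
        self.victim_id = profile.victim_id
        self.condition_id = profile.initial_condition
        self.alive = True
        self.disposition = None  # None | dead | admitted | discharged
        self.location = "site"
        self.death_location = None
        self.arrival_minute = None
        self.priority_key = None
        self.clinical = ClinicalFacet(self)
        self.logistics = LogisticsFacet(self)

    # -- shared state -------------------------------------------------------
    def current_condition(self) -> ClinicalCondition:
        return self.profile.conditions[self.condition_id]

    @property
    def rpm(self) -> int:
        return self.current_condition().rpm

    @property
    def category(self) -> str:
        return self.profile.triage_mix_category

    def set_condition(self, condition_id: str) -> None:
        self.condition_id = condition_id
        cc = self.current_condition()
        if cc.end_kind == "dead":
            self.alive = False
            self.disposition = "dead"
            self.death_location = self.location

    def state_hash(self) -> str:
        payload = json.dumps(
            [
                self.victim_id,
                self.condition_id,
                self.alive,
                self.disposition,
                self.location,
                self.arrival_minute,
                self.priority_key,
            ],
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    # -- trigger propagation (exactly once per event) -----------------------
    def _propagate_treatment(self, skill) -> None:
        self.clinical.treatment_triggers.append(skill)
        if self.clinical.on_treatment is not None:
            self.clinical.on_treatment(skill)

    def _propagate_death(self, time) -> None:
        self.logistics.death_notifications.append(time)
        if self.logistics.on_death is not None:
            self.logistics.on_death(self)


def duplicate_entity(victim) -> tuple:
    """Two handles over one shared victim state.

    The clinical facet drives the monitoring model, the logistics facet the
    response model; each trigger crossing the boundary is delivered exactly
    once.
    """
    entity = victim if isinstance(victim, VictimEntity) else VictimEntity(victim)
    return entity.clinical, entity.logistics


# ---------------------------------------------------------------------------
# geometry and roster
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Geometry:
    """Node distances (km) and vehicle speeds (km/h)."""

    pairs: dict  # frozenset-free: dict[(a, b)] = km, stored both directions
    speeds: dict = field(
        default_factory=lambda: {"ambulance": 60.0, "mmt": 60.0, "bus": 40.0}
    )

    def distance(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        try:
            return self.pairs[(a, b)]
        except KeyError:
            raise KeyError(f"no distance recorded between {a} and {b}")

    def travel_minutes(self, a: str, b: str, vehicle: str = "ambulance") -> float:
        from .response import travel_time

        return travel_time(self.distance(a, b), self.speeds[vehicle])


def _sym(pairs: dict) -> dict:
    out = {}
    for (a, b), d in pairs.items():
        if d < 0:
            raise ValueError("distances must be >= 0")
        out[(a, b)] = float(d)
        out[(b, a)] = float(d)
    return out


@dataclass(frozen=True)
class HCFSpec:
    hcf_id: str
    distance_km: float
    capabilities: tuple = ("general",)


@dataclass(frozen=True)
class ResourceRoster:
    n_ambulances: int = 38
    n_stations: int = 32
    n_mmts: int = 10
    n_rits: int = 2
    station_km: tuple = ()
    mmt_base_km: tuple = ()
    hcfs: tuple = ()

    def __post_init__(self):
        if min(self.n_ambulances, self.n_mmts, self.n_rits, self.n_stations) < 0:
            raise ValueError("roster counts must be >= 0")


def default_roster() -> ResourceRoster:
    """Airport case-study roster: 38 ambulances over 32 stations, 10 MMTs."""
    station_km = tuple(round(2.0 + 1.2 * i, 1) for i in range(32))
    mmt_base_km = (3.0, 5.0, 7.0, 9.0, 10.0, 11.0, 13.0, 15.0, 25.0, 30.0)
    hcfs = (
        HCFSpec("H1", 8.0, ("general",)),
        HCFSpec("H2", 12.0, ("general", "trauma_centre")),
        HCFSpec("H3", 15.0, ("general",)),
        HCFSpec("H4", 20.0, ("general",)),
        HCFSpec("H5", 25.0, ("general", "burn_centre")),
        HCFSpec("H6", 30.0, ("general",)),
    )
    return ResourceRoster(
        station_km=station_km, mmt_base_km=mmt_base_km, hcfs=hcfs
    )


def default_geometry(roster: ResourceRoster | None = None) -> Geometry:
    """Default airport geometry: on-site legs plus a distance ring.

    The CCP sits 25 m from the wreck; the FMP (the airport fire-department
    premises) is one travel minute from the CCP (1 km at 60 km/h).
    """
    roster = roster or default_roster()
    pairs = {
        ("site", "CCP"): 0.025,
        ("CCP", "FMP"): 1.0,
        ("CCP", "NUCA"): 0.2,
        ("NUCA", "NUCF"): 10.0,
    }
    for i, km in enumerate(roster.station_km, start=1):
        pairs[(f"S{i:02d}", "CCP")] = km
        pairs[(f"S{i:02d}", "FMP")] = km
    for i, km in enumerate(roster.mmt_base_km, start=1):
        pairs[(f"M{i:02d}", "CCP")] = km
        pairs[(f"M{i:02d}", "FMP")] = km
    for h in roster.hcfs:
        pairs[(h.hcf_id, "CCP")] = h.distance_km
        pairs[(h.hcf_id, "FMP")] = h.distance_km
    return Geometry(pairs=_sym(pairs))


# ---------------------------------------------------------------------------
# scenario bundle
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    census: Census
    victims: list  # mapped, attributed VictimProfile list
    geometry: Geometry
    roster: ResourceRoster
    seed: int = 0

    def artifact_hash(self) -> str:
        """Stable hash of the scenario content (reproducibility contract)."""
        payload = {
            "census": dataclasses.astuple(self.census),
            "victims": [
                (
                    v.victim_id,
                    v.triage_mix_category,
                    v.ambulatory,
                    v.destination_need,
                    v.initial_condition,
                    sorted(v.conditions),
                    [
                        (t.source, t.target, t.trigger_kind, t.delay, t.required_skill)
                        for t in v.transitions
                    ],
                )
                for v in self.victims
            ],
            "geometry": sorted((a, b, d) for (a, b), d in self.geometry.pairs.items()),
            "roster": (
                self.roster.n_ambulances,
                self.roster.n_mmts,
                self.roster.n_rits,
                self.roster.station_km,
                self.roster.mmt_base_km,
                [(h.hcf_id, h.distance_km, h.capabilities) for h in self.roster.hcfs],
            ),
        }
        return hashlib.sha256(json.dumps(payload, default=str).encode()).hexdigest()


def build_scenario(
    census: Census | None = None,
    library: dict | None = None,
    config: dict | None = None,
    seed: int = 0,
) -> Scenario:
    """Default case-study scenario: census -> profiles -> attributes."""
    census = census or generate_census(None)
    library = library or build_default_profiles(seed=seed)
    victims = map_profiles(census, library, seed=seed)
    victims = assign_attributes(victims, config, seed=seed + 1)
    roster = default_roster()
    return Scenario(
        census=census,
        victims=victims,
        geometry=default_geometry(roster),
        roster=roster,
        seed=seed,
    )
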