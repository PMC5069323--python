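"""Medical response model tests: travel, SAR schedule, dispatch, queue
discipline, distribution, supervision, admission arithmetic, and the
system-level conservation / no-preemption / capacity invariants."""

import math

import pytest

from mcisim import (
    Census,
    DesignPoint,
    ResponseConfig,
    Simulation,
    build_scenario,
    default_geometry,
    dispatch_plan,
    distribute_to_hcf,
    run_default,
    sar_process,
    supervision_assignment,
    travel_time,
)
from mcisim.response import HCFState, PriorityQueue
from mcisim.scenario import HCFSpec, default_roster


class TestTravelTime:
    @pytest.mark.parametrize("km,kmh,minutes", [(30, 60, 30), (0, 50, 0), (17, 85, 12)])
    def test_examples(self, km, kmh, minutes):
        assert travel_time(km, kmh) == pytest.approx(minutes)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            travel_time(10, 0)
        with pytest.raises(ValueError):
            travel_time(-1, 50)

    def test_default_ccp_fmp_leg_is_one_minute(self):
        geometry = default_geometry()
        assert geometry.travel_minutes("CCP", "FMP") == pytest.approx(1.0)


class TestSarProcess:
    def test_schedule_matches_closed_form(self):
        """Independent inverse-cumulative-rate oracle for the medium level."""
        cfg = ResponseConfig()
        times, _ = sar_process(40, "medium", seed=0, config=cfg)
        r0 = cfg.sar_rates["medium"] / 10.0
        r1 = r0 * cfg.hole_multiplier
        cut = cfg.hole_minute
        extracted_by_cut = r0 * (cut - cfg.sar_start)
        for i, t in enumerate(times, start=1):
            if i <= extracted_by_cut:
                expected = cfg.sar_start + i / r0
            else:
                expected = cut + (i - extracted_by_cut) / r1
            assert t == pytest.approx(expected), i

    def test_high_rate_finishes_strictly_earlier(self):
        hi, _ = sar_process(92, "high", seed=3)
        lo, _ = sar_process(92, "low", seed=3)
        assert hi[-1] < lo[-1]

    def test_zero_victims_no_events(self):
        times, order = sar_process(0, "medium", seed=0)
        assert times == [] and order == []

    def test_order_is_seeded_permutation(self):
        _, a = sar_process(10, "medium", seed=5)
        _, b = sar_process(10, "medium", seed=5)
        _, c = sar_process(10, "medium", seed=6)
        assert a == b and sorted(a) == list(range(10)) and a != c

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            sar_process(5, "frantic", seed=0)


@pytest.fixture(scope="module")
def geometry():
    return default_geometry()


class TestDispatchPlan:
    @pytest.mark.parametrize("level", ["low", "medium", "normal", "high"])
    def test_exactly_one_nonworking_commander(self, geometry, level):
        plan = dispatch_plan(level, geometry, default_roster())
        commanders = [m for m in plan["mmts"] if m["role"] == "commander"]
        assert len(commanders) == 1

    def test_initial_wave_is_5_4_2(self, geometry):
        plan = dispatch_plan("normal", geometry, default_roster())
        assert sum(1 for a in plan["ambulances"] if a["depart"] == 0.0) == 5
        assert sum(1 for m in plan["mmts"] if m["depart"] == 0.0) == 4
        assert len(plan["rits"]) == 2

    def test_high_level_sends_seven_working_mmts_in_first_wave(self, geometry):
        plan = dispatch_plan("high", geometry, default_roster())
        first_wave = [m for m in plan["mmts"]
                      if m["role"] != "commander" and 3.0 <= m["arrive"] <= 15.0
                      and m["depart"] == 0.0]
        assert len(first_wave) == 7

    def test_ambulances_depart_from_nearest_stations_first(self, geometry):
        plan = dispatch_plan("normal", geometry, default_roster())
        initial = [a for a in plan["ambulances"] if a["depart"] == 0.0]
        arrivals = [a["arrive"] for a in initial]
        # oracle: the 5 shortest station travel times
        roster = default_roster()
        tts = sorted(geometry.travel_minutes(f"S{i:02d}", "CCP")
                     for i in range(1, roster.n_stations + 1))
        assert arrivals == tts[:5]

    def test_level_exceeding_roster_is_capped(self, geometry):
        plan = dispatch_plan("high", geometry, default_roster())
        assert len(plan["ambulances"]) == 38 and len(plan["mmts"]) == 10

    def test_unknown_level_rejected(self, geometry):
        with pytest.raises(ValueError):
            dispatch_plan("maximal", geometry, default_roster())


class TestQueueDiscipline:
    def _victims(self, n):
        import dataclasses

        from mcisim import build_default_profiles
        from mcisim.scenario import VictimEntity

        lib = build_default_profiles(seed=0)
        return [VictimEntity(dataclasses.replace(lib["T1-A"], victim_id=f"V{i}"))
                for i in range(n)]

    def test_priority_order_lowest_code_first(self):
        q = PriorityQueue()
        a, b, c = self._victims(3)
        q.push(a, code=211110)
        q.push(b, code=106045)
        q.push(c, code=106045)
        assert q.pop() is b  # lowest code wins
        assert q.pop() is c  # equal codes: stable FIFO
        assert q.pop() is a

    def test_fifo_when_triage_disabled(self):
        q = PriorityQueue()
        a, b = self._victims(2)
        q.push(a, code=0)
        q.push(b, code=0)
        assert q.pop() is a and q.pop() is b

    def test_dead_victims_skipped(self):
        q = PriorityQueue()
        a, b = self._victims(2)
        q.push(a, code=1)
        q.push(b, code=2)
        a.alive = False
        assert q.pop() is b and q.pop() is None


class TestSupervisionAssignment:
    def _mmt(self):
        from mcisim.response import Provider

        return Provider("MMT9", "MMT", "treat", location="FMP", present=True)

    def test_emt_level_never_waits(self):
        assert supervision_assignment(None, "emt", "BLS", []) == (None, "EMT")

    def test_physician_nurse_waits_when_no_mmt_idle(self):
        assert supervision_assignment(None, "physician_nurse", "BLS", []) is None
        mmt = self._mmt()
        assert supervision_assignment(None, "physician_nurse", "BLS", [mmt]) == (mmt, "MMT")

    def test_nurse_level_satisfied_by_pit_ambulance(self):
        assert supervision_assignment(None, "nurse", "PIT", []) == (None, "PIT")
        assert supervision_assignment(None, "nurse", "BLS", []) is None

    def test_best_available_uses_idle_physicians(self):
        mmt = self._mmt()
        assert supervision_assignment(None, "best_available", "BLS", [mmt]) == (mmt, "MMT")
        assert supervision_assignment(None, "best_available", "BLS", []) == (None, "EMT")

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            supervision_assignment(None, "maximal", "BLS", [])


class TestDistribution:
    def _hcfs(self, surge=2, n=4):
        return [HCFState(spec=HCFSpec(f"H{i}", 10.0 + i), surge_remaining=surge,
                         rate_per_hour=4.0, weight=surge) for i in range(1, n + 1)]

    class _V:
        pass  # destination_need defaults to general inside distribute_to_hcf

    def test_nearest_first_prefers_closest_open(self):
        hcfs = self._hcfs()
        for _ in range(2):
            assert distribute_to_hcf(self._V(), "nearest_first", hcfs).spec.hcf_id == "H1"
        # closest surge now committed: second closest
        assert distribute_to_hcf(self._V(), "nearest_first", hcfs).spec.hcf_id == "H2"

    def test_round_robin_equal_capacities(self):
        hcfs = self._hcfs()
        picks = [distribute_to_hcf(self._V(), "round_robin", hcfs).spec.hcf_id
                 for _ in range(8)]
        assert {picks.count(f"H{i}") for i in range(1, 5)} == {2}

    def test_destination_need_restricts_choice(self, library):
        import dataclasses

        from mcisim.scenario import VictimEntity

        prof = dataclasses.replace(library["T1-A"], victim_id="V1",
                                   destination_need="trauma_centre")
        v = VictimEntity(prof)
        hcfs = [
            HCFState(spec=HCFSpec("H1", 5.0, ("general",)), surge_remaining=5,
                     rate_per_hour=4, weight=5),
            HCFState(spec=HCFSpec("H2", 20.0, ("general", "trauma_centre")),
                     surge_remaining=5, rate_per_hour=4, weight=5),
        ]
        assert distribute_to_hcf(v, "nearest_first", hcfs).spec.hcf_id == "H2"


class TestHcfAdmission:
    def _sim(self):
        scen = build_scenario(
            census=Census(t1=6, t2=0, t3=0, t4=0, immediate_fatalities=0, uninjured=0),
            seed=0)
        sim = Simulation(scen, DesignPoint(), seed=0)
        sim._setup()
        return sim

    def test_surge_then_hourly_rate(self):
        sim = self._sim()
        hcf = HCFState(spec=HCFSpec("H1", 8.0), surge_remaining=5,
                       rate_per_hour=4.0, weight=5)
        for e in sim.entities:
            sim._hcf_admission(hcf, e)
        admitted_now = [e for e in sim.entities if e.disposition == "admitted"]
        assert len(admitted_now) == 5
        sim.sched.run_until(14.9)
        assert sum(e.disposition == "admitted" for e in sim.entities) == 5
        sim.sched.run_until(15.1)  # 60 / 4 per hour = 15 min later
        assert sum(e.disposition == "admitted" for e in sim.entities) == 6

    def test_infinite_rate_admits_on_arrival(self):
        sim = self._sim()
        hcf = HCFState(spec=HCFSpec("H1", 8.0), surge_remaining=0,
                       rate_per_hour=math.inf, weight=1)
        sim._hcf_admission(hcf, sim.entities[0])
        sim.sched.run_until(0.0)
        assert sim.entities[0].disposition == "admitted"

    def test_admitted_victim_generates_no_further_clinical_events(self):
        sim = self._sim()
        hcf = HCFState(spec=HCFSpec("H1", 8.0), surge_remaining=6,
                       rate_per_hour=4.0, weight=6)
        for e in sim.entities:
            sim._hcf_admission(hcf, e)
        sim.sched.run_until()
        assert all(e.disposition == "admitted" and e.alive for e in sim.entities)


class TestWorkConservation:
    def test_lowest_codes_treated_first_and_provider_reassigned(self):
        """2 treaters, 3 waiting urgent victims at the FMP."""
        scen = build_scenario(
            census=Census(t1=3, t2=0, t3=0, t4=0, immediate_fatalities=0, uninjured=0),
            seed=0)
        sim = Simulation(scen, DesignPoint(), seed=0)
        sim._setup()
        sim.sched._heap.clear()  # isolate the FMP from the arrival choreography
        sim.fmp_ready = 0.0
        # exactly two treaters at the FMP
        for i, prov in enumerate(sim.mmts):
            prov.present = i < 2
            prov.busy = False
            prov.role = "treat"
            prov.location = "FMP"
        a, b, c = sim.entities
        for v, code in [(a, 106010), (b, 104005), (c, 105007)]:
            v.location = "FMP"
            v.priority_key = code
            sim.fmp_treatment.push(v, code=code)
        sim._match_fmp()
        assert b.service and b.service[0] == "treatment"
        assert c.service and c.service[0] == "treatment"
        assert a.service is None  # highest code waits
        # the finishing provider is immediately reassigned to the queue head
        sim.sched.run_until(24.0)  # two consecutive T1 delivery intervals
        starts = {r.subject: dict(r.detail)["start"]
                  for r in sim.log.filter(kind="treatment_complete")}
        assert starts["V001"] == "12.000"


@pytest.fixture(scope="module")
def sp_record(default_scenario):
    return Simulation(default_scenario, DesignPoint(), seed=2).run()


@pytest.fixture(scope="module")
def sr_record(default_scenario):
    return Simulation(default_scenario,
                      DesignPoint(policy="scoop_and_run"), seed=2).run()


class TestFlowRoutes:
    def test_stay_and_play_urgent_route_ccp_fmp_hcf(self, sp_record):
        log = sp_record.event_log
        admitted = [r.subject for r in log.filter(kind="admission")]
        assert admitted, "someone must reach a hospital"
        vid = admitted[0]
        t_fmp = log.first(kind="vehicle_arrival", subject=vid, note="unloaded_fmp")
        t_treat = log.first(kind="treatment_complete", subject=vid, point="FMP")
        t_adm = log.first(kind="admission", subject=vid)
        assert t_fmp.time < t_treat.time < t_adm.time

    def test_walking_wounded_route_nuca_nucf(self, sp_record, default_scenario):
        sim = Simulation(default_scenario, DesignPoint(), seed=2)
        rec = sim.run()
        t3 = [e for e in sim.entities if e.category == "T3"]
        assert t3 and all(e.disposition == "discharged" for e in t3)
        assert all(e.location == "NUCF" for e in t3)

    def test_scoop_and_run_bypasses_fmp(self, sr_record):
        log = sr_record.event_log
        assert not any(dict(r.detail).get("note") == "unloaded_fmp"
                       for r in log.records)
        assert not log.filter(kind="treatment_complete")  or all(
            dict(r.detail).get("point") != "FMP"
            for r in log.filter(kind="treatment_complete"))

    def test_fmp_silent_before_ready_time(self, sp_record):
        ready = sp_record.timestamps["fmp_ready"]
        for r in sp_record.event_log.filter(kind="treatment_complete"):
            d = dict(r.detail)
            if d.get("point") == "FMP":
                assert float(d["start"]) >= ready - 1e-9


class TestSystemInvariants:
    @pytest.mark.parametrize("design", [
        DesignPoint(),
        DesignPoint(policy="scoop_and_run", supervision="physician_nurse"),
        DesignPoint(triage=False, sar="low", hcf_capacity="low"),
        DesignPoint(policy="scoop_and_run", supervision="emt",
                    distribution="round_robin", resources="low"),
    ])
    def test_conservation_of_victims(self, default_scenario, design):
        rec = Simulation(default_scenario, design, seed=5).run()
        assert (rec.total_deaths + rec.admitted + rec.discharged
                + rec.in_system) == rec.injured_total == 205

    def test_no_preemption_of_pickup_assignments(self, default_scenario):
        rec = Simulation(default_scenario, DesignPoint(), seed=9).run()
        pending = {}  # ambulance -> victim loaded
        for r in rec.event_log.records:
            d = dict(r.detail)
            if r.kind == "loading_complete":
                pending[d["ambulance"]] = r.subject
            elif r.kind == "vehicle_departure" and d.get("victim"):
                amb = r.subject
                if amb in pending:
                    assert pending.pop(amb) == d["victim"], "assignment changed"

    def test_capacity_law(self, default_scenario):
        rec = Simulation(default_scenario, DesignPoint(hcf_capacity="low"),
                         seed=9).run()
        surge, rate = ResponseConfig().hcf_levels["low"]
        per_hcf = {}
        for r in rec.event_log.filter(kind="admission"):
            d = dict(r.detail)
            per_hcf.setdefault(d["hcf"], []).append((r.time, d["queued"]))
        for hcf, events in per_hcf.items():
            immediate = [t for t, q in events if q == "no"]
            assert len(immediate) <= surge
            queued = sorted(t for t, q in events if q == "yes")
            for t0, t1 in zip(queued, queued[1:]):
                assert t1 - t0 >= 60.0 / rate - 1e-6

    def test_deterministic_event_log(self, default_scenario):
        a = Simulation(default_scenario, DesignPoint(), seed=4).run()
        b = Simulation(default_scenario, DesignPoint(), seed=4).run()
        assert list(a.event_log.lines()) == list(b.event_log.lines())


class TestDirectionalEffects:
    """Regression tests on the shipped default configuration (seeded)."""

    @staticmethod
    def _mean_deaths(design, reps=10):
        from mcisim.experiments import default_runner, run_seed

        run = default_runner()
        return sum(run(design, run_seed(17, design.policy + str(design), r))
                   for r in range(reps)) / reps

    def test_triage_reduces_mean_mortality(self):
        with_triage = self._mean_deaths(DesignPoint(triage=True))
        without = self._mean_deaths(DesignPoint(triage=False))
        assert with_triage <= without

    def test_faster_extraction_reduces_mean_mortality(self):
        high = self._mean_deaths(DesignPoint(sar="high"))
        low = self._mean_deaths(DesignPoint(sar="low"))
        assert high <= low
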