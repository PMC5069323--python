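"""Unit tests for the victim data model: vital-sign coding, RPM score,
survival lookup, priority codes and the clinical-condition state machine."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcisim import (
    ClinicalCondition,
    PriorityOverflowError,
    Transition,
    VitalSigns,
    code_motor_response,
    code_pulse_rate,
    code_respiratory_rate,
    next_condition,
    priority_code,
    rpm_score,
    survival_probability,
    untreated_death_time,
)
from mcisim.victim import ProfileValidationError

from conftest import VITALS_FOR_RPM, chain_profile


class TestCoding:
    @pytest.mark.parametrize(
        "rr,expected",
        [(0, 0), (1, 1), (9, 1), (36, 2), (100, 2), (25, 3), (35, 3), (30, 3),
         (10, 4), (20, 4), (24, 4)],
    )
    def test_respiratory_rate(self, rr, expected):
        assert code_respiratory_rate(rr) == expected

    @pytest.mark.parametrize(
        "pr,expected",
        [(0, 0), (1, 1), (40, 1), (41, 2), (60, 2), (121, 3), (130, 3), (200, 3),
         (61, 4), (80, 4), (120, 4)],
    )
    def test_pulse_rate(self, pr, expected):
        assert code_pulse_rate(pr) == expected

    @pytest.mark.parametrize(
        "m,expected",
        [("none", 0), ("extends_flexes", 1), ("withdraws", 2),
         ("localizes", 3), ("obeys", 4)],
    )
    def test_motor_response(self, m, expected):
        assert code_motor_response(m) == expected

    @pytest.mark.parametrize("bad", [-1, 2.5, "ten", True])
    def test_rejects_bad_rates(self, bad):
        with pytest.raises(ValueError):
            code_respiratory_rate(bad)
        with pytest.raises(ValueError):
            code_pulse_rate(bad)

    def test_rejects_unknown_motor(self):
        with pytest.raises(ValueError):
            code_motor_response("wiggles")


class TestRpmScore:
    @pytest.mark.parametrize(
        "vitals,expected",
        [
            (VitalSigns(20, 80, "obeys"), 12),  # all three maxima
            (VitalSigns(0, 0, "none"), 0),
            (VitalSigns(30, 130, "withdraws"), 8),  # 3 + 3 + 2
        ],
    )
    def test_examples(self, vitals, expected):
        assert rpm_score(vitals) == expected

    def test_exhaustive_bounds(self):
        """Every combination of coded values yields an RPM in [0, 12]."""
        rr_reps = [0, 5, 40, 30, 16]  # representatives of codes 0..4
        pr_reps = [0, 30, 50, 130, 80]
        motors = ["none", "extends_flexes", "withdraws", "localizes", "obeys"]
        scores = {
            rpm_score(VitalSigns(rr, pr, m))
            for rr in rr_reps
            for pr in pr_reps
            for m in motors
        }
        assert min(scores) == 0 and max(scores) == 12
        assert scores == set(range(13))


class TestSurvivalLookup:
    @pytest.mark.parametrize("rpm,expected", [(12, 98), (6, 63), (0, 5)])
    def test_time_zero_anchors(self, table, rpm, expected):
        assert survival_probability(rpm, 0, table) == expected

    def test_step_function_left_continuous(self, table):
        # within the first bin the t=0 row applies; the row switches at 30
        assert survival_probability(6, 29.99, table) == 63
        assert survival_probability(6, 30, table) == 35
        # beyond the last tabulated row the last row applies
        assert survival_probability(12, 10_000, table) == survival_probability(
            12, 360, table
        )

    def test_monotone_in_both_axes(self, table):
        g = table.grid
        assert (g[1:] <= g[:-1]).all(), "survival must not rise as time passes"
        assert (g[:, 1:] >= g[:, :-1]).all(), "survival must not fall as RPM rises"

    def test_rpm_out_of_range_rejected(self, table):
        with pytest.raises(ValueError):
            survival_probability(13, 0, table)
        with pytest.raises(ValueError):
            survival_probability(-1, 0, table)


class TestPriorityCode:
    @pytest.mark.parametrize(
        "cat,rpm,arrival,expected",
        [(1, 6, 45, 106045), (2, 11, 110, 211110), (1, 0, 0, 100000)],
    )
    def test_examples(self, cat, rpm, arrival, expected):
        assert priority_code(cat, rpm, arrival) == expected

    def test_overflow(self):
        with pytest.raises(PriorityOverflowError):
            priority_code(1, 6, 1000)

    def test_lexicographic_total_order(self):
        """Sorting by code equals lexicographic sort of (category, rpm, arrival)."""
        arrivals = list(range(0, 1000, 37)) + [0, 1, 998, 999]
        triples = [
            (c, r, a) for c in range(1, 5) for r in range(13) for a in arrivals
        ]
        by_code = sorted(triples, key=lambda t: priority_code(*t))
        assert by_code == sorted(triples)


class TestStateMachine:
    def test_untreated_death_time_is_dwell_sum(self):
        prof = chain_profile("X", [(11, 60), (5, 30)], end="dead")
        assert untreated_death_time(prof) == 90

    def test_stabilized_pathway_never_dies(self):
        prof = chain_profile("X", [(12, 45)], end="stabilized", category="T3")
        assert untreated_death_time(prof) == math.inf

    def test_fixture_profile_death_matches_manual_walk(self, library):
        """Walk T1-A's transition list by hand and compare."""
        prof = library["T1-A"]
        # independent walk over the printed transition list
        time_edges = {
            t.source: (t.target, t.delay)
            for t in prof.transitions
            if t.trigger_kind == "time"
        }
        t, cur = 0.0, prof.initial_condition
        while prof.conditions[cur].end_kind == "none":
            target, dwell = time_edges[cur]
            t += dwell
            cur = target
        assert prof.conditions[cur].end_kind == "dead"
        assert untreated_death_time(prof) == t == 60.0

    def test_next_condition_time_and_end_state(self):
        prof = chain_profile("X", [(11, 60), (5, 30)], end="dead")
        assert next_condition("c0", "time", None, prof) == "c1"
        assert next_condition("end", "time", None, prof) is None

    def test_next_condition_treatment_and_substitution(self):
        emt_target = ClinicalCondition.from_vitals(
            "treated", VITALS_FOR_RPM[11], "T1", end_kind="stabilized"
        )
        prof = chain_profile("X", [(11, 60), (5, 30)], end="dead")
        prof.conditions["treated"] = emt_target
        prof.transitions.append(Transition("c0", "treated", "treatment", 5.0, "EMT"))
        prof.validate()
        # dedicated transition
        assert next_condition("c0", "treatment", "EMT", prof) == "treated"
        # a higher-skilled provider may fire the lower-skill transition
        assert next_condition("c0", "treatment", "MMT", prof) == "treated"
        # no substitution downwards: EMT cannot fire an MMT-only transition
        assert next_condition("c1", "treatment", "EMT", prof) is None

    def test_mmt_oblique_transition_in_fixture(self, library):
        prof = library["T1-A"]
        target = next_condition("t0", "treatment", "MMT", prof)
        assert target == "t0.mmt"
        assert prof.conditions[target].rpm >= prof.conditions["t0"].rpm

    def test_validation_rejects_bad_profiles(self):
        prof = chain_profile("X", [(11, 60)], end="dead")
        # missing time transition on a non-end state
        prof.transitions = []
        with pytest.raises(ProfileValidationError):
            prof.validate()
        # dead state with an outgoing transition
        prof2 = chain_profile("X", [(11, 60)], end="dead")
        prof2.transitions.append(Transition("end", "c0", "time", 5.0))
        with pytest.raises(ProfileValidationError):
            prof2.validate()
        # duplicate (source, trigger, skill)
        prof3 = chain_profile("X", [(11, 60)], end="dead")
        prof3.transitions.append(Transition("c0", "end", "time", 9.0))
        with pytest.raises(ProfileValidationError):
            prof3.validate()

    def test_cycle_in_time_pathway_rejected(self):
        prof = chain_profile("X", [(11, 60), (5, 30)], end="dead")
        prof.transitions = [
            Transition("c0", "c1", "time", 60),
            Transition("c1", "c0", "time", 30),
        ]
        with pytest.raises(ProfileValidationError):
            prof.validate()


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    rr=st.integers(min_value=0, max_value=80),
    pr=st.integers(min_value=0, max_value=250),
    m=st.sampled_from(["none", "extends_flexes", "withdraws", "localizes", "obeys"]),
)
def test_rpm_in_range_property(rr, pr, m):
    assert 0 <= rpm_score(VitalSigns(rr, pr, m)) <= 12
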