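import pytest

from mcisim import (
    ClinicalCondition,
    DeteriorationTable,
    Transition,
    VictimProfile,
    VitalSigns,
)
from mcisim.scenario import build_default_profiles, build_scenario

# vitals whose coded sum is a given RPM score (hand-checked against the
# coding table: rr 16 -> 4, rr 30 -> 3, rr 5 -> 1; pr 80 -> 4, pr 130 -> 3;
# motor none/withdraws/localizes/obeys -> 0/2/3/4)
VITALS_FOR_RPM = {
    0: VitalSigns(0, 0, "none"),
    2: VitalSigns(0, 0, "withdraws"),
    4: VitalSigns(0, 0, "obeys"),
    5: VitalSigns(5, 0, "obeys"),
    8: VitalSigns(30, 130, "withdraws"),
    11: VitalSigns(16, 80, "localizes"),
    12: VitalSigns(16, 80, "obeys"),
}


def chain_profile(victim_id, chain, end="dead", category="T1", extra_transitions=()):
    """Profile whose untreated pathway is a simple chain.

    ``chain`` is a list of (rpm, dwell) pairs; the final transition enters a
    dead or stabilized end state.
    """
    conditions, transitions = {}, []
    ids = [f"c{i}" for i in range(len(chain))]
    for cid, (rpm, _) in zip(ids, chain):
        conditions[cid] = ClinicalCondition.from_vitals(
            cid, VITALS_FOR_RPM[rpm], category
        )
    end_id = "end"
    end_vitals = VITALS_FOR_RPM[0] if end == "dead" else VITALS_FOR_RPM[chain[-1][0]]
    conditions[end_id] = ClinicalCondition.from_vitals(
        end_id, end_vitals, category, end_kind=end
    )
    for i, (cid, (_, dwell)) in enumerate(zip(ids, chain)):
        target = ids[i + 1] if i + 1 < len(ids) else end_id
        transitions.append(Transition(cid, target, "time", dwell))
    transitions.extend(extra_transitions)
    prof = VictimProfile(
        victim_id=victim_id,
        triage_mix_category=category,
        ambulatory=category == "T3",
        destination_need="general",
        initial_condition=ids[0],
        conditions=conditions,
        transitions=list(transitions),
    )
    prof.validate()
    return prof


@pytest.fixture(scope="session")
def table():
    return DeteriorationTable.default()


@pytest.fixture(scope="session")
def library():
    return build_default_profiles(seed=0)


@pytest.fixture(scope="session")
def default_scenario():
    return build_scenario(seed=0)
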