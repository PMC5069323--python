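"""Serialization of scenario bundles: census, profile library, geometry,
roster.  All formats are plain structured text (TSV / YAML) so bundles are
diffable and round-trip exactly."""

from __future__ import annotations

import dataclasses
import os

import yaml

from .scenario import Census, Geometry, HCFSpec, ResourceRoster, _sym
from .victim import ClinicalCondition, Transition, VictimProfile, VitalSigns


# -- profile library ----------------------------------------------------------


def profile_to_dict(p: VictimProfile) -> dict:
    return {
        "victim_id": p.victim_id,
        "category": p.triage_mix_category,
        "ambulatory": p.ambulatory,
        "destination_need": p.destination_need,
        "initial_condition": p.initial_condition,
        "conditions": [
            {
                "id": c.condition_id,
                "rr": c.vitals.respiratory_rate,
                "pr": c.vitals.pulse_rate,
                "motor": c.vitals.motor_response,
                "category": c.triage_category,
                "end": c.end_kind,
            }
            for c in sorted(p.conditions.values(), key=lambda c: c.condition_id)
        ],
        "transitions": [
            {
                "source": t.source,
                "target": t.target,
                "trigger": t.trigger_kind,
                "delay": t.delay,
                "skill": t.required_skill,
                "supplies": list(t.required_supplies),
            }
            for t in sorted(
                p.transitions,
                key=lambda t: (t.source, t.trigger_kind, t.required_skill, t.target),
            )
        ],
    }


def profile_from_dict(d: dict) -> VictimProfile:
    conditions = {}
    for c in d["conditions"]:
        conditions[c["id"]] = ClinicalCondition.from_vitals(
            c["id"],
            VitalSigns(c["rr"], c["pr"], c["motor"]),
            c["category"],
            end_kind=c["end"],
        )
    transitions = [
        Transition(t["source"], t["target"], t["trigger"], t["delay"],
                   t["skill"], tuple(t.get("supplies", ())))
        for t in d["transitions"]
    ]
    prof = VictimProfile(
        victim_id=d["victim_id"],
        triage_mix_category=d["category"],
        ambulatory=d["ambulatory"],
        destination_need=d["destination_need"],
        initial_condition=d["initial_condition"],
        conditions=conditions,
        transitions=transitions,
    )
    prof.validate()
    return prof


LIBRARY_SCHEMA_VERSION = 1


def write_library(library: dict, path: str) -> None:
    docs = {
        "schema_version": LIBRARY_SCHEMA_VERSION,
        "profiles": [profile_to_dict(library[k]) for k in sorted(library)],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(docs, fh, sort_keys=True)


def read_library(path: str) -> dict:
    with open(path) as fh:
        docs = yaml.safe_load(fh)
    if docs.get("schema_version") != LIBRARY_SCHEMA_VERSION:
        raise ValueError("unsupported profile library schema version")
    return {d["victim_id"]: profile_from_dict(d) for d in docs["profiles"]}


# -- census -------------------------------------------------------------------


def write_census(census: Census, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("field\tcount\n")
        for f in dataclasses.fields(census):
            fh.write(f"{f.name}\t{getattr(census, f.name)}\n")


def read_census(path: str) -> Census:
    values = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            name, count = line.split("\t")
            values[name] = int(count)
    return Census(**values)


# -- geometry -----------------------------------------------------------------


def write_geometry(geometry: Geometry, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("kind\ta\tb\tvalue\n")
        for name, v in sorted(geometry.speeds.items()):
            fh.write(f"speed\t{name}\t-\t{v}\n")
        seen = set()
        for (a, b), d in sorted(geometry.pairs.items()):
            if (b, a) in seen:
                continue
            seen.add((a, b))
            fh.write(f"distance\t{a}\t{b}\t{d}\n")


def read_geometry(path: str) -> Geometry:
    pairs, speeds = {}, {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            kind, a, b, v = line.rstrip("\n").split("\t")
            if kind == "speed":
                speeds[a] = float(v)
            else:
                pairs[(a, b)] = float(v)
    return Geometry(pairs=_sym(pairs), speeds=speeds)


# -- roster -------------------------------------------------------------------


def write_roster(roster: ResourceRoster, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tid\tvalue\tcapabilities\n")
        for name in ("n_ambulances", "n_stations", "n_mmts", "n_rits"):
            fh.write(f"param\t{name}\t{getattr(roster, name)}\t-\n")
        for i, km in enumerate(roster.station_km, start=1):
            fh.write(f"station\tS{i:02d}\t{km}\t-\n")
        for i, km in enumerate(roster.mmt_base_km, start=1):
            fh.write(f"mmt_base\tM{i:02d}\t{km}\t-\n")
        for h in roster.hcfs:
            fh.write(f"hcf\t{h.hcf_id}\t{h.distance_km}\t{'|'.join(h.capabilities)}\n")


def read_roster(path: str) -> ResourceRoster:
    params, stations, bases, hcfs = {}, [], [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            kind, name, value, caps = line.rstrip("\n").split("\t")
            if kind == "param":
                params[name] = int(value)
            elif kind == "station":
                stations.append(float(value))
            elif kind == "mmt_base":
                bases.append(float(value))
            elif kind == "hcf":
                hcfs.append(HCFSpec(name, float(value), tuple(caps.split("|"))))
    return ResourceRoster(station_km=tuple(stations), mmt_base_km=tuple(bases),
                          hcfs=tuple(hcfs), **params)


# -- bundle -------------------------------------------------------------------

BUNDLE_FILES = ("census.tsv", "profiles.yaml", "geometry.tsv", "roster.tsv")


def write_bundle(path: str, census: Census, library: dict,
                 geometry: Geometry, roster: ResourceRoster) -> None:
    os.makedirs(path, exist_ok=True)
    write_census(census, os.path.join(path, "census.tsv"))
    write_library(library, os.path.join(path, "profiles.yaml"))
    write_geometry(geometry, os.path.join(path, "geometry.tsv"))
    write_roster(roster, os.path.join(path, "roster.tsv"))


def read_bundle(path: str):
    census = read_census(os.path.join(path, "census.tsv"))
    library = read_library(os.path.join(path, "profiles.yaml"))
    geometry = read_geometry(os.path.join(path, "geometry.tsv"))
    roster = read_roster(os.path.join(path, "roster.tsv"))
    return census, library, geometry, roster
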