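"""Scenario configuration: schema, loading and full-report validation.

Validation collects *all* violations (key path + message) instead of failing
at the first, so a config can be repaired in one pass.  Unknown keys are
rejected.
"""

from __future__ import annotations

import copy
import dataclasses
import os
from dataclasses import dataclass

import yaml

from .response import (
    DISTRIBUTIONS,
    HCF_LEVELS,
    POLICIES,
    RESOURCE_LEVELS,
    SAR_LEVELS,
    SUPERVISION_LEVELS,
    DesignPoint,
    ResponseConfig,
)
from .scenario import Census

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "horizon": 720.0,
    "bundle": None,  # optional path to a fixtures bundle directory
    "census": {
        "t1": 26, "t2": 62, "t3": 113, "t4": 4,
        "immediate_fatalities": 5, "uninjured": 40,
    },
    "factors": {
        "policy": "stay_and_play",
        "triage": True,
        "sar": "medium",
        "resources": "normal",
        "supervision": "best_available",
        "distribution": "nearest_first",
        "hcf_capacity": "medium",
    },
    "response": {},  # overrides of ResponseConfig numeric fields
    "destination_fractions": {},
}

_RESPONSE_FIELDS = {f.name for f in dataclasses.fields(ResponseConfig)}
_FACTOR_LEVELS = {
    "policy": POLICIES,
    "sar": SAR_LEVELS,
    "resources": RESOURCE_LEVELS,
    "supervision": SUPERVISION_LEVELS,
    "distribution": DISTRIBUTIONS,
    "hcf_capacity": HCF_LEVELS,
}


class ConfigError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    raw: dict

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def census(self) -> Census:
        return Census(**self.raw["census"])

    def design(self) -> DesignPoint:
        return DesignPoint(**self.raw["factors"])

    def response(self) -> ResponseConfig:
        return ResponseConfig(horizon=float(self.raw["horizon"]),
                              **self.raw["response"])


def _merge(base: dict, override: dict, path: str, violations: list) -> dict:
    out = copy.deepcopy(base)
    for key, value in (override or {}).items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            violations.append(f"{where}: unknown key")
            continue
        if isinstance(base[key], dict) and key != "destination_fractions":
            if not isinstance(value, dict):
                violations.append(f"{where}: expected a mapping")
                continue
            out[key] = _merge(base[key], value, where, violations)
        else:
            out[key] = value
    return out


def load_config(path: str | None) -> ScenarioConfig:
    """Load and merge a YAML config over the defaults.

    ``path`` of ``None`` or ``"default"`` yields the built-in case-study
    config.  Raises :class:`ConfigError` listing every violation.
    """
    if path in (None, "default"):
        return ScenarioConfig(copy.deepcopy(DEFAULT_CONFIG))
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    violations: list = []
    merged = _merge(DEFAULT_CONFIG, user, "", violations)
    cfg = ScenarioConfig(merged)
    violations += validate(cfg)
    if violations:
        raise ConfigError("invalid config:\n" + "\n".join(violations))
    return cfg


def validate(config: ScenarioConfig | dict) -> list:
    """Return the complete list of violations (empty when valid)."""
    raw = config.raw if isinstance(config, ScenarioConfig) else config
    v: list = []
    # structural: unknown keys
    _merge(DEFAULT_CONFIG, raw, "", v)

    census = raw.get("census", {})
    for key, value in census.items():
        if not isinstance(value, int) or value < 0:
            v.append(f"census.{key}: must be a non-negative integer")

    horizon = raw.get("horizon", 720.0)
    if not isinstance(horizon, (int, float)) or horizon <= 0:
        v.append("horizon: must be a positive number of minutes")
    elif horizon >= 1000:
        v.append(
            "horizon: arrival minutes beyond 999 overflow the 3-digit "
            "priority-code field (keep the horizon under 1000 min)"
        )

    factors = raw.get("factors", {})
    for name, levels in _FACTOR_LEVELS.items():
        if name in factors and factors[name] not in levels:
            v.append(f"factors.{name}: {factors[name]!r} not in {levels}")
    if "triage" in factors and not isinstance(factors["triage"], bool):
        v.append("factors.triage: must be true or false")

    for key, value in raw.get("response", {}).items():
        if key not in _RESPONSE_FIELDS:
            v.append(f"response.{key}: unknown response parameter")
        elif isinstance(value, (int, float)) and value < 0:
            v.append(f"response.{key}: must be >= 0")

    for cat, fr in (raw.get("destination_fractions") or {}).items():
        if cat not in ("T1", "T2", "T3", "T4"):
            v.append(f"destination_fractions.{cat}: unknown category")
            continue
        for name, x in fr.items():
            if name not in ("trauma_centre", "burn_centre"):
                v.append(f"destination_fractions.{cat}.{name}: unknown destination")
            elif not (0 <= x <= 1):
                v.append(f"destination_fractions.{cat}.{name}: fraction outside [0, 1]")
        if sum(fr.values()) > 1 + 1e-9:
            v.append(f"destination_fractions.{cat}: fractions sum above 1")

    bundle = raw.get("bundle")
    if bundle:
        v += validate_bundle(bundle)
    return v


def validate_bundle(path: str) -> list:
    """Validate a fixtures bundle directory; returns violations."""
    from .io import BUNDLE_FILES

    v: list = []
    if not os.path.isdir(path):
        return [f"bundle: {path} is not a directory"]
    for name in BUNDLE_FILES:
        if not os.path.exists(os.path.join(path, name)):
            v.append(f"bundle.{name}: missing")
    geom = os.path.join(path, "geometry.tsv")
    if os.path.exists(geom):
        with open(geom) as fh:
            fh.readline()
            for i, line in enumerate(fh, start=2):
                kind, a, b, value = line.rstrip("\n").split("\t")
                if kind == "distance" and float(value) < 0:
                    v.append(f"bundle.geometry.tsv:{i}: negative distance {a}-{b}")
                if kind == "speed" and float(value) <= 0:
                    v.append(f"bundle.geometry.tsv:{i}: non-positive speed {a}")
    return v
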