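"""Full-factorial experiment harness over the seven interventional factors.

The factor space crosses operational policy (2) x triage (2) x SAR rate (3)
x pre-hospital resources (4) x transport supervision (4) x hospital
distribution (2) x hospital treatment capacity (3) = 1152 design points.
Replications are seeded deterministically per (base seed, design, replication)
so sweeps are reproducible and order-independent.  Reporting is standard:
per-factor descriptive tables, one-way ANOVA with eta-squared, post-hoc
Scheffe tests, and the per-design stay-and-play minus scoop-and-run mortality
difference.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats

from .response import (
    DISTRIBUTIONS,
    HCF_LEVELS,
    POLICIES,
    RESOURCE_LEVELS,
    SAR_LEVELS,
    SUPERVISION_LEVELS,
    DesignPoint,
    ResponseConfig,
    Simulation,
)
from .scenario import Scenario, assign_attributes, build_default_profiles, default_geometry, default_roster, generate_census, map_profiles

FACTORS = ("policy", "triage", "sar", "resources", "supervision",
           "distribution", "hcf_capacity")


@dataclass(frozen=True)
class FactorSpace:
    policy: tuple = POLICIES
    triage: tuple = (True, False)
    sar: tuple = SAR_LEVELS
    resources: tuple = RESOURCE_LEVELS
    supervision: tuple = SUPERVISION_LEVELS
    distribution: tuple = DISTRIBUTIONS
    hcf_capacity: tuple = HCF_LEVELS

    def size(self) -> int:
        n = 1
        for f in fields(self):
            n *= len(getattr(self, f.name))
        return n


def build_factorial(space: FactorSpace | None = None) -> list:
    """Exhaustive Cartesian product of factor levels, deterministic order."""
    space = space or FactorSpace()
    level_lists = []
    for f in fields(space):
        levels = tuple(getattr(space, f.name))
        if not levels:
            raise ValueError(f"factor {f.name} has no levels")
        level_lists.append(levels)
    designs = []
    for i, combo in enumerate(itertools.product(*level_lists), start=1):
        kwargs = dict(zip(FACTORS, combo))
        designs.append(DesignPoint(design_id=f"D{i:04d}", **kwargs))
    return designs


def run_seed(base_seed: int, design_id: str, replication: int) -> int:
    """Stable per-run seed: CRC32 of (base_seed, design id, replication)."""
    return zlib.crc32(f"{base_seed}:{design_id}:{replication}".encode()) & 0x7FFFFFFF


def default_runner(config: ResponseConfig | None = None):
    """Simulator callable ``(design, seed) -> total deaths``.

    The profile library is a fixture shared across runs; replication
    randomness enters through profile mapping, attribute assignment and the
    SAR extraction order.
    """
    library = build_default_profiles(seed=0)
    census = generate_census(None)
    roster = default_roster()
    geometry = default_geometry(roster)
    config = config or ResponseConfig()

    def run(design: DesignPoint, seed: int) -> int:
        victims = map_profiles(census, library, seed=seed)
        victims = assign_attributes(victims, None, seed=seed + 1)
        scenario = Scenario(census=census, victims=victims, geometry=geometry,
                            roster=roster, seed=seed)
        return Simulation(scenario, design=design, seed=seed, config=config).run().total_deaths

    return run


def run_replications(designs, n_reps: int, base_seed: int, runner=None) -> pd.DataFrame:
    """Run every design ``n_reps`` times; one row per (design, replication).

    Simulator failures are recorded per run (``error`` column, NaN deaths)
    without aborting the sweep.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if runner is None:
        runner = default_runner()
    rows = []
    for d in designs:
        for rep in range(n_reps):
            seed = run_seed(base_seed, d.design_id, rep)
            row = {"design_id": d.design_id, **{f: getattr(d, f) for f in FACTORS},
                   "replication": rep, "seed": seed}
            try:
                row["total_deaths"] = runner(d, seed)
                row["error"] = ""
            except Exception as exc:  # noqa: BLE001 - per-run failure is data
                row["total_deaths"] = np.nan
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_by_factor(results: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Descriptive statistics of total deaths per level of one factor."""
    if results.empty:
        raise ValueError("results table is empty")
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    g = results.groupby(factor, sort=True)["total_deaths"]
    out = pd.DataFrame(
        {
            "mean": g.mean(),
            "median": g.median(),
            "sd": g.std(ddof=1).fillna(0.0),
            "min": g.min(),
            "max": g.max(),
            "n": g.count(),
        }
    )
    out.index.name = factor
    return out


@dataclass
class AnovaResult:
    factor: str
    F: float
    p: float
    eta_squared: float
    df_between: int
    df_within: int
    degenerate: bool = False


def anova_oneway(results: pd.DataFrame, factor: str) -> AnovaResult:
    """One-way ANOVA of total deaths on one factor's levels.

    ``eta_squared`` is SS_factor / SS_total.  Observations are individual
    replication runs.  A zero within- and between-group variance is flagged
    as degenerate rather than raising.
    """
    groups = [g.dropna().to_numpy(dtype=float)
              for _, g in results.groupby(factor)["total_deaths"]]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 levels with >= 2 observations each")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_total = float(((all_values - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    k, n = len(groups), len(all_values)
    if ss_total == 0.0:
        return AnovaResult(factor, float("nan"), float("nan"), 0.0,
                           k - 1, n - k, degenerate=True)
    F, p = stats.f_oneway(*groups)
    return AnovaResult(factor, float(F), float(p), ss_between / ss_total,
                       k - 1, n - k, degenerate=not np.isfinite(F))


def scheffe(results: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Post-hoc Scheffe pairwise comparisons after a one-way ANOVA."""
    grouped = {lvl: g.dropna().to_numpy(dtype=float)
               for lvl, g in results.groupby(factor)["total_deaths"]}
    levels = sorted(grouped, key=str)
    k = len(levels)
    if k < 2:
        raise ValueError("need >= 2 levels")
    n_total = sum(len(g) for g in grouped.values())
    mse = sum(((g - g.mean()) ** 2).sum() for g in grouped.values()) / (n_total - k)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        ga, gb = grouped[a], grouped[b]
        diff = ga.mean() - gb.mean()
        if mse == 0.0:
            rows.append({"level_a": a, "level_b": b, "diff": diff,
                         "F": float("inf") if diff else 0.0, "p": 0.0 if diff else 1.0})
            continue
        se2 = mse * (1.0 / len(ga) + 1.0 / len(gb))
        F_s = diff ** 2 / (se2 * (k - 1))
        p = float(stats.f.sf(F_s, k - 1, n_total - k))
        rows.append({"level_a": a, "level_b": b, "diff": diff, "F": float(F_s), "p": p})
    return pd.DataFrame(rows)


def delta_deaths(results: pd.DataFrame) -> pd.Series:
    """Per matched design: mean deaths(stay_and_play) - mean deaths(scoop_and_run).

    Designs are matched on all factors except policy; means are taken over
    replications.  A negative value means stay-and-play saved lives there.
    """
    other = [f for f in FACTORS if f != "policy"]
    means = results.groupby(other + ["policy"])["total_deaths"].mean().unstack("policy")
    if not {"stay_and_play", "scoop_and_run"} <= set(means.columns):
        raise ValueError("results must contain both policies")
    delta = means["stay_and_play"] - means["scoop_and_run"]
    delta.name = "delta_deaths"
    return delta
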