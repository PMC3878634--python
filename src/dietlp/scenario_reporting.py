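"""Food-supply scenarios and observed-vs-modeled pattern reports.

The headline perturbation is an across-the-board 10% reduction of the
sodium content of every food: each category's per-100 g sodium is scaled by
0.90 while everything else is untouched.  Because every diet's sodium total
scales by the same factor, the (Na, K) feasibility region maps exactly via
(Na, K) -> (0.9 Na, K) — the scenario shifts the region left without
reshaping attainable potassium.

``run_full_analysis`` orchestrates the whole per-group pipeline (filters,
aggregation, constraints, ratio-anchored max-K, sodium sweep, min-deviation
pattern, guideline verdicts) across scenarios and writes CSV/JSON artifacts
with a manifest.  ``compare_patterns`` emits the observed-vs-optimized
MyPyramid table (cup-eq / oz-eq servings, energy, total weight, SoFAS).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .aggregation import (
    ObservedPattern,
    aggregate_categories,
    consumption_percentiles,
    filter_foods,
    filter_individuals,
    observed_pattern,
)
from .constraints import apply_ratio_constraint, build_constraint_set
from .feasibility import (
    check_guideline_compatibility,
    max_k_at_ratio,
    sweep_sodium,
    DEFAULT_STEP_MG,
)
from .lp_core import OPTIMAL, LPSolution, solve_min_deviation
from .nutrients import (
    DEFAULT_NA_K_RATIO,
    ENERGY,
    POTASSIUM,
    POTASSIUM_GOAL_MG,
    SODIUM,
    SODIUM_LIMIT_MG,
    SODIUM_LIMIT_STRICT_MG,
)


@dataclass(frozen=True)
class Scenario:
    """A uniform perturbation of the food supply's sodium content."""

    tag: str = "baseline"
    sodium_multiplier: float = 1.0

    def __post_init__(self):
        if not (0 < self.sodium_multiplier <= 1):
            raise ValueError("sodium_multiplier must be in (0, 1]")


BASELINE = Scenario()
SODIUM_CUT_10PCT = Scenario("na_minus_10pct", 0.90)


def reduce_sodium(categories: pd.DataFrame,
                  multiplier: float) -> pd.DataFrame:
    """Scale every category's per-100 g sodium by ``multiplier`` (in
    (0, 1]); all other columns untouched."""
    if not (0 < multiplier <= 1):
        raise ValueError("multiplier must be in (0, 1]")
    out = categories.copy()
    out[SODIUM] = out[SODIUM] * multiplier
    return out


# --------------------------------------------------------------------------
# pattern comparison (Table-style report)
# --------------------------------------------------------------------------

_PYRAMID_ROWS = [
    ("Fruits", "fruit_cup", "cup/d"),
    ("Vegetables", "vegetable_cup", "cup/d"),
    ("Total grains", "grain_total_oz", "oz eq/d"),
    ("Whole grains", "grain_whole_oz", "oz eq/d"),
    ("Refined grains", "grain_refined_oz", "oz eq/d"),
    ("Meat and beans", "meat_beans_oz", "oz eq/d"),
    ("Milk", "milk_cup", "cup/d"),
    ("Oils", "oils_g", "g/d"),
    ("SoFAS", "sofas_kcal", "kcal/d"),
]


@dataclass
class PatternComparison:
    group: str
    table: pd.DataFrame  # row, observed, modeled, units


def compare_patterns(observed: ObservedPattern,
                     modeled: LPSolution,
                     group: str | None = None) -> PatternComparison:
    """Observed vs optimized food pattern in MyPyramid units.

    Rows: energy (kcal/d), total weight (kg/d), the MyPyramid food groups
    (cup-eq / oz-eq), oils (g/d) and SoFAS (kcal/d).
    """
    if modeled.status != OPTIMAL:
        raise ValueError("modeled solution is not optimal")
    group = group or observed.group
    if observed.group != group:
        raise ValueError(
            f"group mismatch: {observed.group!r} vs {group!r}")
    rows = [
        ("Energy", float(observed.totals[ENERGY]),
         float(modeled.totals[ENERGY]), "kcal/d"),
        ("Total weight", float(observed.amounts.sum()) / 1000.0,
         float(modeled.amounts.sum()) / 1000.0, "kg/d"),
    ]
    for label, col, units in _PYRAMID_ROWS:
        rows.append((label, float(observed.totals[col]),
                     float(modeled.totals[col]), units))
    rows.append(("Sodium", float(observed.totals[SODIUM]),
                 float(modeled.totals[SODIUM]), "mg/d"))
    rows.append(("Potassium", float(observed.totals[POTASSIUM]),
                 float(modeled.totals[POTASSIUM]), "mg/d"))
    table = pd.DataFrame(rows,
                         columns=["row", "observed", "modeled", "units"])
    return PatternComparison(group=group, table=table)


# --------------------------------------------------------------------------
# full analysis
# --------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Configuration of a full per-group, per-scenario analysis run."""

    groups: list = field(default_factory=list)   # empty = all groups present
    ratio: float = DEFAULT_NA_K_RATIO
    sodium_limit_mg: float = SODIUM_LIMIT_MG
    sodium_limit_strict_mg: float = SODIUM_LIMIT_STRICT_MG
    potassium_goal_mg: float = POTASSIUM_GOAL_MG
    step_mg: float = DEFAULT_STEP_MG
    scenarios: list = field(
        default_factory=lambda: [BASELINE, SODIUM_CUT_10PCT])
    vitamin_e_override: bool = True

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        scen = [Scenario(s["tag"], s["sodium_multiplier"])
                for s in d.pop("scenarios", [])]
        cfg = cls(**d)
        if scen:
            cfg.scenarios = scen
        return cfg

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "ratio": self.ratio,
            "sodium_limit_mg": self.sodium_limit_mg,
            "sodium_limit_strict_mg": self.sodium_limit_strict_mg,
            "potassium_goal_mg": self.potassium_goal_mg,
            "step_mg": self.step_mg,
            "scenarios": [
                {"tag": s.tag, "sodium_multiplier": s.sodium_multiplier}
                for s in self.scenarios
            ],
            "vitamin_e_override": self.vitamin_e_override,
        }


def run_group_scenario(categories, profile, bounds, observed, config,
                       scenario: Scenario) -> dict:
    """One group x scenario cell of the analysis: anchor point, sweep,
    min-deviation pattern, guideline verdicts."""
    cats = reduce_sodium(categories, scenario.sodium_multiplier)
    cs = build_constraint_set(profile, bounds,
                              vitamin_e_override=config.vitamin_e_override)
    na_star, k_star, anchor = max_k_at_ratio(cats, cs, config.ratio)
    start = na_star if anchor.status == OPTIMAL else config.sodium_limit_mg
    region = sweep_sodium(cats, cs, start_mg=start, step_mg=config.step_mg,
                          group=profile.group, scenario=scenario.tag)
    mindev = solve_min_deviation(cats, apply_ratio_constraint(cs, config.ratio),
                                 observed)
    verdicts = {}
    for label, limit in (("na2300_k4700", config.sodium_limit_mg),
                         ("na1500_k4700", config.sodium_limit_strict_mg)):
        if region.empty:
            verdicts[label] = {"compatible": False, "witness": None}
        else:
            ok, wit = check_guideline_compatibility(
                region, limit, config.potassium_goal_mg)
            verdicts[label] = {"compatible": bool(ok),
                               "witness": list(wit) if wit else None}
    return {
        "group": profile.group,
        "scenario": scenario.tag,
        "anchor": {"status": anchor.status, "na_mg": na_star, "k_mg": k_star},
        "region": region,
        "min_deviation": mindev,
        "comparison": (compare_patterns(observed, mindev)
                       if mindev.status == OPTIMAL else None),
        "verdicts": verdicts,
    }


def run_full_analysis(
    foods: pd.DataFrame,
    intakes: pd.DataFrame,
    profiles: list,
    config: AnalysisConfig | None = None,
    out_dir=None,
) -> dict:
    """Run the whole pipeline for every requested group and scenario.

    Returns a report bundle ``{(group, scenario_tag): cell}`` plus a
    manifest; when ``out_dir`` is given, regions / solutions / comparison
    tables are written as CSV and JSON with the config echoed.
    """
    config = config or AnalysisConfig()
    foods_f = filter_foods(foods)
    intakes_f = filter_individuals(intakes, foods)
    groups = config.groups or [
        p.group for p in profiles
        if (intakes_f["sex_age_group"] == p.group).any()
    ]
    prof_by_group = {p.group: p for p in profiles}
    missing = [g for g in groups if g not in prof_by_group]
    if missing:
        raise ValueError(f"no GroupProfile for groups: {missing}")

    cells = {}
    manifest = {"config": config.to_dict(), "cells": []}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for group in groups:
        profile = prof_by_group[group]
        categories = aggregate_categories(intakes_f, foods_f, group)
        bounds = consumption_percentiles(intakes_f, foods_f, group)
        observed = observed_pattern(intakes_f, categories, group)
        for scenario in config.scenarios:
            cell = run_group_scenario(categories, profile, bounds, observed,
                                      config, scenario)
            cells[(group, scenario.tag)] = cell
            entry = {
                "group": group, "scenario": scenario.tag,
                "anchor": cell["anchor"],
                "na_interval_mg": list(cell["region"].na_interval),
                "verdicts": cell["verdicts"],
                "min_deviation_status": cell["min_deviation"].status,
            }
            manifest["cells"].append(entry)
            if out is not None:
                stem = f"{group.replace('>', 'gt')}_{scenario.tag}"
                cell["region"].to_csv(out / f"region_{stem}.csv")
                cell["region"].to_json(out / f"region_{stem}.json")
                cell["min_deviation"].to_json(out / f"mindev_{stem}.json")
                if cell["comparison"] is not None:
                    cell["comparison"].table.to_csv(
                        out / f"comparison_{stem}.csv", index=False)
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh)
    return {"cells": cells, "manifest": manifest}
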