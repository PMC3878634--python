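"""Linear constraint system for diet optimization.

A :class:`ConstraintSet` holds the modeling constraints in domain terms —
an energy equality at the group's estimated energy requirement (EER), DRI
nutrient min/max rows, consumption bounds on taxonomy nodes (10th/90th
percentile for major groups, 75th percentile caps for subgroups and
categories), and the optional Na:K mass-ratio equality and fixed-sodium
level used by the feasibility sweeps.  :func:`to_lp_problem` lowers the set
to dense matrix form over a concrete category list, keeping a provenance
label per row.

Variables are continuous daily amounts in grams with lower bound 0; the
nutrient coefficient of category *i* in a row is ``per100g_i / 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .nutrients import (
    DEFAULT_NA_K_RATIO,
    ENERGY,
    NUTRIENT_COLUMNS,
    SODIUM,
    POTASSIUM,
    TAXONOMY_TIERS,
)

#: Vitamin E minimum (mg/d) applied to young men, who report essentially no
#: vegetable-oil consumption; assumes one tablespoon of oil per day.
VITAMIN_E_OVERRIDE_MG = 13.0
VITAMIN_E_OVERRIDE_GROUP = "M20-30"


@dataclass(frozen=True)
class NutrientRow:
    nutrient: str           # a column of the per-100 g panel
    sense: str              # ">=" or "<="
    bound: float            # daily amount in the nutrient's native units
    units: str = ""

    def __post_init__(self):
        if self.sense not in (">=", "<="):
            raise ValueError(f"sense must be '>=' or '<=', got {self.sense!r}")
        if self.nutrient not in NUTRIENT_COLUMNS:
            raise ValueError(f"unknown nutrient {self.nutrient!r}")


@dataclass(frozen=True)
class GroupBound:
    node_id: str            # taxonomy node (major / subgroup / category id)
    tier: str               # one of TAXONOMY_TIERS
    lower: float | None     # g/d or None
    upper: float | None     # g/d or None

    def __post_init__(self):
        if self.tier not in TAXONOMY_TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")


@dataclass
class ConstraintSet:
    group: str
    energy_kcal: float
    nutrient_rows: list = field(default_factory=list)
    group_bounds: list = field(default_factory=list)
    ratio: float | None = None          # Na:K mass ratio equality
    fixed_sodium_mg: float | None = None

    def __post_init__(self):
        if self.energy_kcal <= 0:
            raise ValueError("energy_kcal must be positive")
        if self.ratio is not None and self.ratio <= 0:
            raise ValueError("ratio must be positive")
        seen = set()
        for row in self.nutrient_rows:
            key = (row.nutrient, row.sense)
            if key in seen:
                raise ValueError(f"duplicate nutrient row {key}")
            seen.add(key)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "energy_kcal": self.energy_kcal,
            "nutrient_rows": [
                {"nutrient": r.nutrient, "sense": r.sense, "bound": r.bound,
                 "units": r.units}
                for r in self.nutrient_rows
            ],
            "group_bounds": [
                {"node_id": b.node_id, "tier": b.tier, "lower": b.lower,
                 "upper": b.upper}
                for b in self.group_bounds
            ],
            "ratio": self.ratio,
            "fixed_sodium_mg": self.fixed_sodium_mg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConstraintSet":
        return cls(
            group=d["group"],
            energy_kcal=d["energy_kcal"],
            nutrient_rows=[NutrientRow(**r) for r in d["nutrient_rows"]],
            group_bounds=[GroupBound(**b) for b in d["group_bounds"]],
            ratio=d.get("ratio"),
            fixed_sodium_mg=d.get("fixed_sodium_mg"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ConstraintSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_constraint_set(
    profile,
    bounds: pd.DataFrame | None = None,
    vitamin_e_override: bool = False,
    sodium_limit_mg: float | None = None,
    potassium_goal_mg: float | None = None,
) -> ConstraintSet:
    """Assemble the group's constraint set.

    Energy is an equality at ``profile.eer_kcal``.  Each DRI table entry
    becomes a ``>=`` row (min) and/or ``<=`` row (max).  Major groups are
    bounded by [p10, p90], subgroups and categories by [0, p75] from the
    percentile table.  ``vitamin_e_override`` raises the vitamin E minimum
    to 13 mg/d for the young-men group.  Sodium / potassium guideline rows
    are off by default (the sweeps own sodium) and added only on request.
    """
    rows: list[NutrientRow] = []
    for r in profile.dri.itertuples(index=False):
        lo = None if pd.isna(r.min) else float(r.min)
        hi = None if pd.isna(r.max) else float(r.max)
        if lo is not None and hi is not None and lo > hi:
            raise ValueError(f"DRI row {r.nutrient}: min {lo} > max {hi}")
        if lo is not None:
            rows.append(NutrientRow(r.nutrient, ">=", lo))
        if hi is not None:
            rows.append(NutrientRow(r.nutrient, "<=", hi))
    if vitamin_e_override and profile.group == VITAMIN_E_OVERRIDE_GROUP:
        rows = [r for r in rows
                if not (r.nutrient == "vitamin_e_mg" and r.sense == ">=")]
        rows.append(NutrientRow("vitamin_e_mg", ">=", VITAMIN_E_OVERRIDE_MG,
                                "mg/d"))
    if sodium_limit_mg is not None:
        rows.append(NutrientRow(SODIUM, "<=", float(sodium_limit_mg), "mg/d"))
    if potassium_goal_mg is not None:
        rows.append(NutrientRow(POTASSIUM, ">=", float(potassium_goal_mg),
                                "mg/d"))

    gbounds: list[GroupBound] = []
    if bounds is not None:
        for b in bounds.itertuples(index=False):
            if b.tier == "major":
                gbounds.append(GroupBound(b.node_id, "major",
                                          float(b.p10), float(b.p90)))
            else:
                gbounds.append(GroupBound(b.node_id, b.tier, None,
                                          float(b.p75)))
    return ConstraintSet(
        group=profile.group,
        energy_kcal=float(profile.eer_kcal),
        nutrient_rows=rows,
        group_bounds=gbounds,
    )


def apply_ratio_constraint(cs: ConstraintSet, r: float = DEFAULT_NA_K_RATIO
                           ) -> ConstraintSet:
    """Add the Na:K mass-ratio equality ``Na - r*K = 0`` (daily mg)."""
    if r <= 0:
        raise ValueError("ratio must be positive")
    return replace(cs, ratio=float(r))


def drop_ratio_constraint(cs: ConstraintSet) -> ConstraintSet:
    return replace(cs, ratio=None)


def fix_sodium(cs: ConstraintSet, s: float,
               exclusive: bool = True) -> ConstraintSet:
    """Fix total daily sodium to ``s`` mg.  With ``exclusive`` (default) any
    ratio constraint is removed, matching the sweep protocol in which the
    ratio is dropped before sodium is stepped down. Idempotent in ``s``."""
    if s < 0:
        raise ValueError("fixed sodium must be non-negative")
    return replace(cs, fixed_sodium_mg=float(s),
                   ratio=None if exclusive else cs.ratio)


# --------------------------------------------------------------------------
# lowering to matrices
# --------------------------------------------------------------------------

@dataclass
class LPProblem:
    """Dense matrix form of a ConstraintSet over an ordered category list.

    ``eq_labels`` / ``ub_labels`` trace every row back to the ConstraintSet
    entry that produced it.
    """

    variables: list
    A_eq: np.ndarray
    b_eq: np.ndarray
    A_ub: np.ndarray
    b_ub: np.ndarray
    eq_labels: list
    ub_labels: list


def to_lp_problem(categories: pd.DataFrame, cs: ConstraintSet) -> LPProblem:
    """Lower ``cs`` to A_eq/b_eq, A_ub/b_ub over ``categories`` (ordered by
    their appearance in the table). Coefficients are per gram, i.e.
    per-100 g values divided by 100."""
    cat = categories.set_index("category_id")
    variables = list(cat.index)
    per_g = {n: cat[n].to_numpy(float) / 100.0 for n in NUTRIENT_COLUMNS}

    A_eq, b_eq, eq_labels = [], [], []
    A_ub, b_ub, ub_labels = [], [], []

    A_eq.append(per_g[ENERGY]); b_eq.append(cs.energy_kcal)
    eq_labels.append("energy")

    for r in cs.nutrient_rows:
        row = per_g[r.nutrient]
        if r.sense == "<=":
            A_ub.append(row); b_ub.append(r.bound)
            ub_labels.append(f"nutrient:{r.nutrient}<=")
        else:
            A_ub.append(-row); b_ub.append(-r.bound)
            ub_labels.append(f"nutrient:{r.nutrient}>=")

    key_of = {"major": "major_group_id", "subgroup": "subgroup_id",
              "category": None}
    for b in cs.group_bounds:
        if b.tier == "category":
            member = (cat.index == b.node_id).astype(float)
        else:
            member = (cat[key_of[b.tier]] == b.node_id).to_numpy(float)
        if not member.any():
            continue  # node not represented in this group's variable list
        if b.upper is not None:
            A_ub.append(member); b_ub.append(b.upper)
            ub_labels.append(f"bound:{b.node_id}<=")
        if b.lower is not None and b.lower > 0:
            A_ub.append(-member); b_ub.append(-b.lower)
            ub_labels.append(f"bound:{b.node_id}>=")

    if cs.ratio is not None:
        A_eq.append(per_g[SODIUM] - cs.ratio * per_g[POTASSIUM])
        b_eq.append(0.0)
        eq_labels.append(f"ratio:{cs.ratio}")
    if cs.fixed_sodium_mg is not None:
        A_eq.append(per_g[SODIUM]); b_eq.append(cs.fixed_sodium_mg)
        eq_labels.append("fixed_sodium")

    return LPProblem(
        variables=variables,
        A_eq=np.array(A_eq), b_eq=np.array(b_eq),
        A_ub=np.array(A_ub) if A_ub else np.empty((0, len(variables))),
        b_ub=np.array(b_ub) if b_ub else np.empty(0),
        eq_labels=eq_labels, ub_labels=ub_labels,
    )


def from_lp_problem(problem: LPProblem, categories: pd.DataFrame,
                    group: str) -> ConstraintSet:
    """Reconstruct a ConstraintSet from matrix form using row provenance.

    Inverse of :func:`to_lp_problem` up to bounds on taxonomy nodes that are
    unrepresented in ``categories`` (those produce no rows and cannot be
    recovered).
    """
    cat = categories.set_index("category_id")
    majors = set(cat["major_group_id"])
    subs = set(cat["subgroup_id"])

    energy = ratio = fixed_na = None
    for label, b in zip(problem.eq_labels, problem.b_eq):
        if label == "energy":
            energy = float(b)
        elif label.startswith("ratio:"):
            ratio = float(label.split(":", 1)[1])
        elif label == "fixed_sodium":
            fixed_na = float(b)

    rows: list[NutrientRow] = []
    gb: dict[str, list] = {}
    for label, b in zip(problem.ub_labels, problem.b_ub):
        kind, rest = label.split(":", 1)
        sense = rest[-2:]
        node = rest[:-2]
        if kind == "nutrient":
            rows.append(NutrientRow(node, sense, b if sense == "<=" else -b))
        else:
            lo, hi = gb.get(node, [None, None])
            if sense == "<=":
                hi = float(b)
            else:
                lo = float(-b)
            gb[node] = [lo, hi]
    gbounds = []
    for node, (lo, hi) in gb.items():
        tier = ("major" if node in majors
                else "subgroup" if node in subs else "category")
        gbounds.append(GroupBound(node, tier, lo, hi))
    return ConstraintSet(group=group, energy_kcal=energy,
                         nutrient_rows=rows, group_bounds=gbounds,
                         ratio=ratio, fixed_sodium_mg=fixed_na)


def to_mps(problem: LPProblem, objective: np.ndarray, path,
           name: str = "DIETLP", maximize: bool = False) -> None:
    """Write the problem in fixed-format MPS for cross-solver checks.

    MPS has no native maximize flag, so a maximization objective is written
    negated and the caller negates the optimum back.
    """
    c = -objective if maximize else objective
    with open(path, "w") as fh:
        fh.write(f"NAME          {name}\n")
        fh.write("ROWS\n")
        fh.write(" N  COST\n")
        for i in range(len(problem.b_eq)):
            fh.write(f" E  EQ{i}\n")
        for i in range(len(problem.b_ub)):
            fh.write(f" L  UB{i}\n")
        fh.write("COLUMNS\n")
        for j, var in enumerate(problem.variables):
            col = f"X{j}"
            entries = [("COST", c[j])]
            entries += [(f"EQ{i}", problem.A_eq[i, j])
                        for i in range(len(problem.b_eq))]
            entries += [(f"UB{i}", problem.A_ub[i, j])
                        for i in range(len(problem.b_ub))]
            for row, val in entries:
                if val != 0.0:
                    fh.write(f"    {col:<10}{row:<10}{val:.12g}\n")
        fh.write("RHS\n")
        for i, v in enumerate(problem.b_eq):
            if v != 0.0:
                fh.write(f"    RHS       EQ{i:<8}{v:.12g}\n")
        for i, v in enumerate(problem.b_ub):
            if v != 0.0:
                fh.write(f"    RHS       UB{i:<8}{v:.12g}\n")
        fh.write("BOUNDS\nENDATA\n")
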