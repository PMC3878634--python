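"""Seeded synthetic food-composition and intake-survey generators.

The generators emulate the statistical structure of a US national intake
survey joined to a food-composition database: six sex-age groups, a
three-tier food taxonomy (categories nested in subgroups nested in 9 major
groups), right-skewed consumption distributions, and nutrient profiles in
which sodium concentrates in grain/mixed-dish/prepared foods while potassium
concentrates in fruits, vegetables and dairy.  Nutrient densities are drawn
from per-major-group log-normal templates, which keeps every value positive
and right-skewed like real composition data.

Everything is deterministic for a fixed seed.  A registry of tiny
hand-solvable fixtures (``make_toy_fixture``) backs the analytic tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .nutrients import (
    DRI_NUTRIENTS,
    ENERGY,
    FEMALE_GROUPS,
    LOW_ENERGY_DENSITY_KCAL,
    NUTRIENT_COLUMNS,
    POTASSIUM,
    PROFILE_COLUMNS,
    PYRAMID_COLUMNS,
    SEX_AGE_GROUPS,
    SODIUM,
)

# --------------------------------------------------------------------------
# taxonomy
# --------------------------------------------------------------------------

#: The 9 major food groups, with the number of subgroups allotted to each
#: (39 subgroups total by default).
DEFAULT_MAJOR_GROUPS = {
    "milk_products": 4,
    "meat_fish_beans": 6,
    "grains": 6,
    "fruits": 4,
    "vegetables": 6,
    "fats_oils": 3,
    "sweets": 3,
    "beverages": 3,
    "mixed_dishes": 4,
}


@dataclass(frozen=True)
class TaxonomySpec:
    """Counts per taxonomy tier: categories nested in subgroups nested in
    major groups."""

    majors: dict = field(default_factory=lambda: dict(DEFAULT_MAJOR_GROUPS))
    n_categories: int = 100

    @property
    def n_subgroups(self) -> int:
        return sum(self.majors.values())

    @property
    def n_majors(self) -> int:
        return len(self.majors)


def build_taxonomy(spec: TaxonomySpec, rng: np.random.Generator) -> pd.DataFrame:
    """Materialize a taxonomy table: one row per category with its subgroup
    and major group. Categories are spread over subgroups proportionally,
    every subgroup getting at least one category."""
    if spec.n_categories < spec.n_subgroups:
        raise ValueError(
            f"n_categories ({spec.n_categories}) must be >= number of "
            f"subgroups ({spec.n_subgroups})"
        )
    sub_rows = []
    for major, n_sub in spec.majors.items():
        for j in range(n_sub):
            sub_rows.append((f"{major}.s{j + 1}", major))
    subs = pd.DataFrame(sub_rows, columns=["subgroup_id", "major_group_id"])

    # one category per subgroup, remainder multinomially over subgroups
    extra = rng.multinomial(
        spec.n_categories - len(subs), np.full(len(subs), 1.0 / len(subs))
    )
    cat_rows = []
    for (sub, major), n_extra in zip(subs.itertuples(index=False), extra):
        for k in range(1 + n_extra):
            cat_rows.append((f"{sub}.c{k + 1}", sub, major))
    return pd.DataFrame(
        cat_rows, columns=["category_id", "subgroup_id", "major_group_id"]
    )


# --------------------------------------------------------------------------
# composition templates
# --------------------------------------------------------------------------

# Per-major-group log-normal templates for composition per 100 g.
# "med" is the median of the log-normal; sigma is the log-scale spread.
# Sodium is high in grains / mixed dishes / prepared foods, potassium high
# in fruits, vegetables and dairy — the gradient the feasibility analysis
# exploits.
_T = {
    # major: energy, Na, K, fiber, vitA, vitC, vitE, Ca, Fe, Mg, Zn, folate
    "fruits": dict(energy=55, na=4, k=220, fiber=2.0, va=30, vc=30, ve=0.5,
                   ca=15, fe=0.3, mg=12, zn=0.12, fol=15,
                   prot_frac=0.04, fat_frac=0.05, sat_of_fat=0.2,
                   sugar_of_carb=0.15, solid_of_fat=0.1),
    "vegetables": dict(energy=42, na=45, k=280, fiber=2.6, va=220, vc=22,
                       ve=0.8, ca=40, fe=0.8, mg=20, zn=0.4, fol=45,
                       prot_frac=0.12, fat_frac=0.08, sat_of_fat=0.2,
                       sugar_of_carb=0.02, solid_of_fat=0.1),
    "grains": dict(energy=250, na=420, k=120, fiber=3.0, va=2, vc=0.3,
                   ve=0.6, ca=40, fe=2.5, mg=30, zn=1.0, fol=60,
                   prot_frac=0.13, fat_frac=0.18, sat_of_fat=0.3,
                   sugar_of_carb=0.08, solid_of_fat=0.5),
    "milk_products": dict(energy=95, na=75, k=160, fiber=0.05, va=50, vc=1,
                          ve=0.1, ca=150, fe=0.1, mg=12, zn=0.5, fol=8,
                          prot_frac=0.22, fat_frac=0.40, sat_of_fat=0.65,
                          sugar_of_carb=0.10, solid_of_fat=0.9),
    "meat_fish_beans": dict(energy=200, na=350, k=260, fiber=0.4, va=10,
                            vc=1, ve=0.4, ca=20, fe=1.6, mg=22, zn=2.6,
                            fol=15, prot_frac=0.40, fat_frac=0.45,
                            sat_of_fat=0.4, sugar_of_carb=0.02,
                            solid_of_fat=0.8),
    "fats_oils": dict(energy=650, na=280, k=40, fiber=0.05, va=50, vc=0.1,
                      ve=8.0, ca=10, fe=0.2, mg=2, zn=0.1, fol=2,
                      prot_frac=0.01, fat_frac=0.95, sat_of_fat=0.35,
                      sugar_of_carb=0.05, solid_of_fat=0.5),
    "sweets": dict(energy=380, na=160, k=80, fiber=1.0, va=10, vc=1, ve=0.8,
                   ca=40, fe=1.0, mg=15, zn=0.4, fol=10,
                   prot_frac=0.05, fat_frac=0.35, sat_of_fat=0.5,
                   sugar_of_carb=0.55, solid_of_fat=0.8),
    "beverages": dict(energy=26, na=9, k=60, fiber=0.05, va=2, vc=10,
                      ve=0.03, ca=8, fe=0.1, mg=5, zn=0.05, fol=5,
                      prot_frac=0.03, fat_frac=0.02, sat_of_fat=0.3,
                      sugar_of_carb=0.7, solid_of_fat=0.1),
    "mixed_dishes": dict(energy=180, na=450, k=180, fiber=1.6, va=40, vc=5,
                         ve=1.0, ca=60, fe=1.5, mg=20, zn=1.2, fol=30,
                         prot_frac=0.18, fat_frac=0.35, sat_of_fat=0.4,
                         sugar_of_carb=0.05, solid_of_fat=0.6),
}

#: log-scale spread of densities within a major group
_SIGMA = {"beverages": 1.2}
_SIGMA_DEFAULT = 0.45

# typical single-food daily portion (g) when consumed, per major group;
# drawn log-normally so per-category consumption is right-skewed
_PORTION_MED = {
    "fruits": 120, "vegetables": 90, "grains": 90, "milk_products": 200,
    "meat_fish_beans": 110, "fats_oils": 12, "sweets": 50,
    "beverages": 330, "mixed_dishes": 250,
}


def _lognormal(rng, median, sigma, size):
    return rng.lognormal(np.log(median), sigma, size)


@dataclass
class GeneratorConfig:
    """Tunable rates of the synthetic world (documented defaults)."""

    #: fraction of non-low-energy foods flagged with each special class
    excluded_fractions: dict = field(
        default_factory=lambda: {
            "baby_food": 0.01,
            "alcohol": 0.015,
            "supplement": 0.01,
            "chewing_gum": 0.005,
        }
    )
    #: fraction of women generated as pregnant
    pregnant_fraction: float = 0.02
    #: fraction of individuals with implausibly low reported energy (<600)
    low_energy_fraction: float = 0.02
    #: number of distinct foods per individual, inclusive range
    foods_per_individual: tuple = (20, 60)
    #: relative spread of individual energy targets around the group EER
    energy_cv: float = 0.18

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "excluded_fractions": dict(self.excluded_fractions),
                    "pregnant_fraction": self.pregnant_fraction,
                    "low_energy_fraction": self.low_energy_fraction,
                    "foods_per_individual": list(self.foods_per_individual),
                    "energy_cv": self.energy_cv,
                },
                fh,
            )


#: Default estimated energy requirements (kcal/d) per sex-age group.
DEFAULT_EER = {
    "M20-30": 2800.0,
    "M31-50": 2600.0,
    "M>50": 2000.0,
    "F20-30": 2200.0,
    "F31-50": 2000.0,
    "F>50": 1800.0,
}


def default_dri_table() -> pd.DataFrame:
    """Synthetic daily DRI bounds (columns nutrient, min, max; native units).

    These are configuration defaults chosen to be binding-but-satisfiable in
    the synthetic world, not claims about real DRIs.  Sodium/potassium
    guideline rows are intentionally absent: the feasibility sweeps own
    those, and experiments toggle them explicitly.
    """
    rows = [
        ("protein_g", 50.0, None),
        ("fiber_g", 18.0, None),
        ("vitamin_a_ug", 500.0, None),
        ("vitamin_c_mg", 55.0, None),
        ("vitamin_e_mg", 9.0, None),
        ("calcium_mg", 800.0, None),
        ("iron_mg", 8.0, None),
        ("magnesium_mg", 260.0, None),
        ("zinc_mg", 8.0, None),
        ("folate_ug", 300.0, None),
    ]
    return pd.DataFrame(rows, columns=["nutrient", "min", "max"])


@dataclass
class GroupProfile:
    """Per sex-age group: energy requirement, DRI bounds, head count."""

    group: str
    eer_kcal: float
    dri: pd.DataFrame
    n_individuals: int = 0

    def __post_init__(self):
        if self.eer_kcal <= 0:
            raise ValueError("eer_kcal must be positive")
        both = self.dri.dropna(subset=["min", "max"])
        if (both["min"] > both["max"]).any():
            raise ValueError("DRI table has min > max")


# --------------------------------------------------------------------------
# food database
# --------------------------------------------------------------------------

def generate_food_database(
    n_foods: int = 260,
    taxonomy_spec: TaxonomySpec | None = None,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Generate a food-composition table: one row per food code with
    taxonomy keys, per-100 g nutrient vector, MyPyramid equivalents and an
    exclusion flag.

    Deterministic for a fixed seed. Foods are assigned round-robin to
    categories so every category has at least one member when
    ``n_foods >= n_categories``.
    """
    spec = taxonomy_spec or TaxonomySpec()
    cfg = config or GeneratorConfig()
    if n_foods < spec.n_categories:
        raise ValueError(
            f"n_foods ({n_foods}) must be >= category count "
            f"({spec.n_categories})"
        )
    rng = np.random.default_rng(seed)
    taxonomy = build_taxonomy(spec, rng)

    # round-robin assignment over a shuffled category list
    order = rng.permutation(len(taxonomy))
    idx = np.tile(order, int(np.ceil(n_foods / len(order))))[:n_foods]
    cats = taxonomy.iloc[idx].reset_index(drop=True)

    rows = []
    for i, cat in enumerate(cats.itertuples(index=False)):
        t = _T[cat.major_group_id]
        sig = _SIGMA.get(cat.major_group_id, _SIGMA_DEFAULT)
        energy = float(_lognormal(rng, t["energy"], sig, 1)[0])
        # macro split: protein and fat as (jittered) energy shares, carbs as
        # the remainder, so macros stay consistent with energy
        pf = np.clip(t["prot_frac"] * rng.lognormal(0, 0.3), 0, 0.8)
        ff = np.clip(t["fat_frac"] * rng.lognormal(0, 0.3), 0, 0.95)
        if pf + ff > 0.98:
            scale = 0.98 / (pf + ff)
            pf, ff = pf * scale, ff * scale
        protein = energy * pf / 4.0
        fat = energy * ff / 9.0
        carb = max(energy - 4.0 * protein - 9.0 * fat, 0.0) / 4.0
        sat = fat * np.clip(t["sat_of_fat"] * rng.lognormal(0, 0.25), 0, 1)
        solid_fat = fat * np.clip(
            t["solid_of_fat"] * rng.lognormal(0, 0.25), 0, 1
        )
        added_sugar = carb * np.clip(
            t["sugar_of_carb"] * rng.lognormal(0, 0.3), 0, 1
        )
        nut = {
            ENERGY: energy,
            SODIUM: float(_lognormal(rng, t["na"], sig, 1)[0]),
            POTASSIUM: float(_lognormal(rng, t["k"], sig, 1)[0]),
            "protein_g": protein,
            "carbohydrate_g": carb,
            "fat_g": fat,
            "sat_fat_g": sat,
            "fiber_g": float(_lognormal(rng, t["fiber"], sig, 1)[0]),
            "vitamin_a_ug": float(_lognormal(rng, t["va"], sig, 1)[0]),
            "vitamin_c_mg": float(_lognormal(rng, t["vc"], sig, 1)[0]),
            "vitamin_e_mg": float(_lognormal(rng, t["ve"], sig, 1)[0]),
            "calcium_mg": float(_lognormal(rng, t["ca"], sig, 1)[0]),
            "iron_mg": float(_lognormal(rng, t["fe"], sig, 1)[0]),
            "magnesium_mg": float(_lognormal(rng, t["mg"], sig, 1)[0]),
            "zinc_mg": float(_lognormal(rng, t["zn"], sig, 1)[0]),
            "folate_ug": float(_lognormal(rng, t["fol"], sig, 1)[0]),
            "added_sugar_g": added_sugar,
            "solid_fat_g": solid_fat,
        }
        rows.append(
            {
                "food_code": f"f{i + 1:05d}",
                "name": f"{cat.category_id} food {i + 1}",
                "category_id": cat.category_id,
                "subgroup_id": cat.subgroup_id,
                "major_group_id": cat.major_group_id,
                **nut,
                **_pyramid_equivalents(cat.major_group_id, nut, rng),
            }
        )
    foods = pd.DataFrame(rows)

    # exclusion flags: the low-energy-density flag is a deterministic rule,
    # the other classes are random with configurable rates
    flags = np.where(
        foods[ENERGY] < LOW_ENERGY_DENSITY_KCAL, "low_energy_density", "none"
    ).astype(object)
    eligible = flags == "none"
    u = rng.random(len(foods))
    lo = 0.0
    for cls, frac in cfg.excluded_fractions.items():
        pick = eligible & (u >= lo) & (u < lo + frac)
        flags[pick] = cls
        lo += frac
    foods["excluded_class"] = flags
    return foods


def _pyramid_equivalents(major: str, nut: dict, rng) -> dict:
    """MyPyramid serving equivalents per 100 g, driven by the major group.

    SoFAS kcal is derived from the food's own solid fat and added sugar
    (9 and 4 kcal/g) so the accounting identity holds by construction.
    """
    eq = dict.fromkeys(PYRAMID_COLUMNS, 0.0)
    jitter = rng.lognormal(0, 0.2)
    if major == "fruits":
        eq["fruit_cup"] = 0.43 * jitter
    elif major == "vegetables":
        eq["vegetable_cup"] = 0.45 * jitter
    elif major == "grains":
        total = 1.1 * jitter
        whole = total * rng.beta(1.2, 3.0)
        eq["grain_total_oz"] = total
        eq["grain_whole_oz"] = whole
        eq["grain_refined_oz"] = total - whole
    elif major == "meat_fish_beans":
        eq["meat_beans_oz"] = 2.8 * jitter
    elif major == "milk_products":
        eq["milk_cup"] = 0.42 * jitter
    elif major == "fats_oils":
        eq["oils_g"] = 55.0 * jitter
    elif major == "mixed_dishes":
        eq["vegetable_cup"] = 0.12 * jitter
        total = 0.5 * jitter
        whole = total * rng.beta(1.0, 4.0)
        eq["grain_total_oz"] = total
        eq["grain_whole_oz"] = whole
        eq["grain_refined_oz"] = total - whole
        eq["meat_beans_oz"] = 0.9 * jitter
    eq["sofas_kcal"] = 9.0 * nut["solid_fat_g"] + 4.0 * nut["added_sugar_g"]
    return eq


# --------------------------------------------------------------------------
# intake survey
# --------------------------------------------------------------------------

def generate_intake_survey(
    foods: pd.DataFrame,
    group_sizes: dict | None = None,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    eer: dict | None = None,
    dri: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[GroupProfile]]:
    """Generate a one-day intake survey over the six sex-age groups.

    Each individual consumes 20-60 distinct foods with log-normal gram
    amounts (right-skewed) scaled so their daily energy matches a target
    drawn around the group EER; a configurable fraction of individuals is
    pregnant (women only) or reports implausibly low energy, to exercise
    the exclusion filters.

    Returns the intake table (one row per individual x food) and one
    :class:`GroupProfile` per group.
    """
    if foods is None or len(foods) == 0:
        raise ValueError("foods table is empty")
    cfg = config or GeneratorConfig()
    sizes = dict.fromkeys(SEX_AGE_GROUPS, 100) if group_sizes is None else group_sizes
    missing = set(SEX_AGE_GROUPS) - set(sizes)
    if missing:
        raise ValueError(f"group_sizes missing groups: {sorted(missing)}")
    eer = dict(DEFAULT_EER) if eer is None else eer
    dri = default_dri_table() if dri is None else dri
    rng = np.random.default_rng(seed)

    # stable per-food popularity weights (heavy-tailed, survey-like)
    popularity = rng.lognormal(0, 1.0, len(foods))
    popularity /= popularity.sum()
    portion_med = foods["major_group_id"].map(_PORTION_MED).to_numpy(float)
    energy100 = foods[ENERGY].to_numpy(float)

    records = []
    profiles = []
    person = 0
    lo_n, hi_n = cfg.foods_per_individual
    for group in SEX_AGE_GROUPS:
        n = int(sizes[group])
        profiles.append(
            GroupProfile(group=group, eer_kcal=float(eer[group]),
                         dri=dri.copy(), n_individuals=n)
        )
        for _ in range(n):
            person += 1
            pid = f"p{person:06d}"
            k = int(rng.integers(lo_n, min(hi_n, len(foods)) + 1))
            chosen = rng.choice(len(foods), size=k, replace=False, p=popularity)
            grams = _lognormal(rng, 1.0, 0.8, k) * portion_med[chosen]
            energy = float(grams @ energy100[chosen]) / 100.0
            if rng.random() < cfg.low_energy_fraction:
                target = rng.uniform(300.0, 580.0)
            else:
                target = rng.normal(eer[group], cfg.energy_cv * eer[group])
                target = max(target, 650.0)
            if energy > 0:
                grams *= target / energy
            pregnant = (
                group in FEMALE_GROUPS and rng.random() < cfg.pregnant_fraction
            )
            codes = foods["food_code"].to_numpy()[chosen]
            for code, g in zip(codes, grams):
                records.append((pid, group, pregnant, code, float(g)))
    intakes = pd.DataFrame(
        records,
        columns=["individual_id", "sex_age_group", "pregnant", "food_code",
                 "grams_per_day"],
    )
    return intakes, profiles


# --------------------------------------------------------------------------
# toy fixtures
# --------------------------------------------------------------------------

def _toy_food(code, category, subgroup, major, energy, na, k, fiber=0.0,
              **pyr):
    row = {
        "food_code": code, "name": code, "category_id": category,
        "subgroup_id": subgroup, "major_group_id": major,
        "excluded_class": "none",
    }
    row.update(dict.fromkeys(NUTRIENT_COLUMNS, 0.0))
    row.update(dict.fromkeys(PYRAMID_COLUMNS, 0.0))
    row[ENERGY], row[SODIUM], row[POTASSIUM] = energy, na, k
    row["fiber_g"] = fiber
    row.update(pyr)
    return row


#: Registry of hand-solvable fixtures.
#:
#: toy2 — two foods, energy equality 2000 kcal/d, no other nutrient rows:
#:   F1: 50 kcal, 20 mg Na, 300 mg K per 100 g
#:   F2: 250 kcal, 500 mg Na, 100 mg K per 100 g
#: The energy plane is the segment x1 = (2000 - 2.5*x2/100*100)... in grams:
#: 0.5*x1 + 2.5*x2 = 2000 with x2 in [0, 800] g, giving the closed forms
#: Na in [800, 4000] mg/d and K = 12000 - 3.5*(Na - 800) mg/d.
#:
#: toy3 — toy2 plus F3 (150 kcal, 100 mg Na, 200 mg K, 6 g fiber per 100 g;
#: F1 carries 3 g fiber) and one DRI row: fiber >= 25 g/d.
TOY_FIXTURES = ("toy2", "toy3")


def make_toy_fixture(name: str):
    """Return ``(foods, intakes, profile)`` for a registered fixture.

    The intake tables are tiny (3 individuals) and chosen so that the
    observed group-mean diet lies exactly on the fixture's energy plane.
    """
    if name not in TOY_FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; known fixtures: {list(TOY_FIXTURES)}"
        )
    f1 = _toy_food("F1", "c.f1", "s.f1", "vegetables", 50.0, 20.0, 300.0,
                   fiber=3.0, vegetable_cup=0.45)
    f2 = _toy_food("F2", "c.f2", "s.f2", "grains", 250.0, 500.0, 100.0,
                   grain_total_oz=1.0, grain_refined_oz=1.0)
    dri = pd.DataFrame(columns=["nutrient", "min", "max"])
    if name == "toy2":
        foods = pd.DataFrame([f1, f2])
        # group means: F1 2000 g, F2 400 g -> exactly 2000 kcal
        rows = [
            ("i1", "M31-50", False, "F1", 2000.0),
            ("i1", "M31-50", False, "F2", 400.0),
            ("i2", "M31-50", False, "F1", 1000.0),
            ("i2", "M31-50", False, "F2", 600.0),
            ("i3", "M31-50", False, "F1", 3000.0),
            ("i3", "M31-50", False, "F2", 200.0),
        ]
    else:  # toy3
        f3 = _toy_food("F3", "c.f3", "s.f3", "mixed_dishes", 150.0, 100.0,
                       200.0, fiber=6.0)
        foods = pd.DataFrame([f1, f2, f3])
        dri = pd.DataFrame(
            [("fiber_g", 25.0, None)], columns=["nutrient", "min", "max"]
        )
        rows = [
            ("i1", "M31-50", False, "F1", 1500.0),
            ("i1", "M31-50", False, "F2", 300.0),
            ("i1", "M31-50", False, "F3", 333.3333333333333),
            ("i2", "M31-50", False, "F1", 1000.0),
            ("i2", "M31-50", False, "F2", 500.0),
            ("i2", "M31-50", False, "F3", 166.66666666666666),
            ("i3", "M31-50", False, "F1", 2000.0),
            ("i3", "M31-50", False, "F2", 100.0),
            ("i3", "M31-50", False, "F3", 500.0),
        ]
    intakes = pd.DataFrame(
        rows,
        columns=["individual_id", "sex_age_group", "pregnant", "food_code",
                 "grams_per_day"],
    )
    profile = GroupProfile(group="M31-50", eer_kcal=2000.0, dri=dri,
                           n_individuals=3)
    return foods, intakes, profile


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def write_dataset(out_dir, foods, intakes, profiles, config=None) -> None:
    """Write the generated tables as CSV (plus the generator config as YAML)
    with documented headers."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    foods.to_csv(out / "foods.csv", index=False)
    intakes.to_csv(out / "intakes.csv", index=False)
    prof_rows = [
        {"group": p.group, "eer_kcal": p.eer_kcal,
         "n_individuals": p.n_individuals}
        for p in profiles
    ]
    pd.DataFrame(prof_rows).to_csv(out / "group_profiles.csv", index=False)
    profiles[0].dri.to_csv(out / "dri.csv", index=False)
    (config or GeneratorConfig()).to_yaml(out / "generator_config.yaml")


def read_dataset(in_dir):
    """Read back a dataset written by :func:`write_dataset`."""
    from pathlib import Path

    d = Path(in_dir)
    foods = pd.read_csv(d / "foods.csv")
    intakes = pd.read_csv(d / "intakes.csv")
    prof = pd.read_csv(d / "group_profiles.csv")
    dri = pd.read_csv(d / "dri.csv")
    profiles = [
        GroupProfile(group=r.group, eer_kcal=float(r.eer_kcal), dri=dri,
                     n_individuals=int(r.n_individuals))
        for r in prof.itertuples(index=False)
    ]
    return foods, intakes, profiles
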