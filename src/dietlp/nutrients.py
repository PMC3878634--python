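"""Shared schema constants: nutrient panel, MyPyramid columns, taxonomy tiers.

All composition values are stored per 100 g of food; daily totals are
``amount_g * per100g / 100``. Units follow the conventions of US food
composition tables (FNDDS-style): energy in kcal, minerals in mg or ug,
macronutrients in g.
"""

from __future__ import annotations

ENERGY = "energy_kcal"
SODIUM = "sodium_mg"
POTASSIUM = "potassium_mg"

#: DRI-panel nutrients (beyond energy / sodium / potassium) carried by every
#: food record, with their per-100 g units implied by the column suffix.
DRI_NUTRIENTS = [
    "protein_g",
    "carbohydrate_g",
    "fat_g",
    "sat_fat_g",
    "fiber_g",
    "vitamin_a_ug",
    "vitamin_c_mg",
    "vitamin_e_mg",
    "calcium_mg",
    "iron_mg",
    "magnesium_mg",
    "zinc_mg",
    "folate_ug",
    "added_sugar_g",
    "solid_fat_g",
]

#: Full nutrient vector of a food record / food category.
NUTRIENT_COLUMNS = [ENERGY, SODIUM, POTASSIUM] + DRI_NUTRIENTS

#: MyPyramid equivalents per 100 g. SoFAS = calories from solid fats and
#: added sugars (9 kcal/g and 4 kcal/g respectively).
PYRAMID_COLUMNS = [
    "fruit_cup",
    "vegetable_cup",
    "grain_total_oz",
    "grain_whole_oz",
    "grain_refined_oz",
    "meat_beans_oz",
    "milk_cup",
    "oils_g",
    "sofas_kcal",
]

PROFILE_COLUMNS = NUTRIENT_COLUMNS + PYRAMID_COLUMNS

#: The six sex-age groups modeled.
SEX_AGE_GROUPS = ["M20-30", "M31-50", "M>50", "F20-30", "F31-50", "F>50"]

FEMALE_GROUPS = [g for g in SEX_AGE_GROUPS if g.startswith("F")]

EXCLUDED_CLASSES = [
    "none",
    "baby_food",
    "alcohol",
    "supplement",
    "chewing_gum",
    "low_energy_density",
]

#: Foods under this energy density (kcal/100 g) are flagged and excluded
#: from modeling (water, coffee, tea and the like).
LOW_ENERGY_DENSITY_KCAL = 10.0

#: Energy intake below which an individual's record is excluded (kcal/d).
MIN_PLAUSIBLE_ENERGY_KCAL = 600.0

#: Guideline levels: sodium upper limits (general population and the
#: stricter level for older / at-risk adults) and the potassium goal, mg/d.
SODIUM_LIMIT_MG = 2300.0
SODIUM_LIMIT_STRICT_MG = 1500.0
POTASSIUM_GOAL_MG = 4700.0

#: Guideline-implied Na:K mass ratio, 2300/4700.
DEFAULT_NA_K_RATIO = SODIUM_LIMIT_MG / POTASSIUM_GOAL_MG

TAXONOMY_TIERS = ("major", "subgroup", "category")
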