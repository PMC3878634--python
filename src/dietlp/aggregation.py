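"""Exclusion filters and collapse of individual foods into food categories.

Individual-level filters drop pregnant women and implausibly low energy
reporters (< 600 kcal/d); food-level filters drop baby foods, alcohol,
supplements, chewing gum and foods below 10 kcal/100 g energy density.
Surviving foods are collapsed, per sex-age group, into food categories whose
per-100 g profile is the consumption-weighted mean of member foods (weights =
total grams consumed within the group), together with the consumption
distribution statistics that later become LP bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nutrients import (
    ENERGY,
    MIN_PLAUSIBLE_ENERGY_KCAL,
    PROFILE_COLUMNS,
)

OBS_STAT_COLUMNS = ["p10", "p75", "p90", "mean_consumers", "n_consumers",
                    "mean_all"]


@dataclass
class ObservedPattern:
    """The observed group-mean diet: per-category g/d plus nutrient totals."""

    group: str
    amounts: pd.Series  # category_id -> g/d (mean over all individuals)
    totals: pd.Series   # nutrient + pyramid daily totals


def _require_known_foods(intakes: pd.DataFrame, foods: pd.DataFrame) -> None:
    unknown = set(intakes["food_code"]) - set(foods["food_code"])
    if unknown:
        raise ValueError(
            f"intake rows reference unknown food codes: {sorted(unknown)[:5]}"
        )


def filter_individuals(
    intakes: pd.DataFrame, foods: pd.DataFrame, verbose: bool = False
) -> pd.DataFrame:
    """Drop pregnant individuals and those reporting < 600 kcal/d.

    Energy is computed from the (unfiltered) foods table, so the plausibility
    screen reflects everything the person reported eating. Returns the
    filtered intake table; logs counts dropped per reason when ``verbose``.
    """
    _require_known_foods(intakes, foods)
    e = foods.set_index("food_code")[ENERGY]
    kcal = intakes["grams_per_day"] * intakes["food_code"].map(e) / 100.0
    per_person = kcal.groupby(intakes["individual_id"]).sum()
    low = set(per_person.index[per_person < MIN_PLAUSIBLE_ENERGY_KCAL])
    pregnant = set(intakes.loc[intakes["pregnant"], "individual_id"])
    drop = low | pregnant
    if verbose:
        print(
            f"filter_individuals: dropped {len(pregnant)} pregnant, "
            f"{len(low)} below {MIN_PLAUSIBLE_ENERGY_KCAL:.0f} kcal/d "
            f"({len(drop)} unique)"
        )
    return intakes[~intakes["individual_id"].isin(drop)].reset_index(drop=True)


def filter_foods(foods: pd.DataFrame) -> pd.DataFrame:
    """Keep only foods with ``excluded_class == 'none'``. Idempotent."""
    return foods[foods["excluded_class"] == "none"].reset_index(drop=True)


def _joined(intakes: pd.DataFrame, foods: pd.DataFrame, group: str):
    # intake rows for foods that the food filter removed drop out of the
    # join here; referential integrity against the *unfiltered* table is
    # enforced earlier, in filter_individuals
    sub = intakes[intakes["sex_age_group"] == group]
    sub = sub[sub["food_code"].isin(foods["food_code"])]
    return sub.merge(
        foods[["food_code", "category_id", "subgroup_id", "major_group_id"]
              + PROFILE_COLUMNS],
        on="food_code",
    )


def aggregate_categories(
    intakes: pd.DataFrame, foods: pd.DataFrame, group: str
) -> pd.DataFrame:
    """Collapse the group's consumed foods into food categories.

    Each category's per-100 g vector is the mean of member foods' vectors
    weighted by total grams consumed of each food within the group, so
    mass-weighted nutrient totals are conserved by construction. Categories
    never consumed by the group are omitted: the LP variable list is
    group-specific.

    Returns one row per category: taxonomy keys, weighted per-100 g profile,
    and consumption statistics (p10/p75/p90/mean over consumers, number of
    consumers, mean over all individuals in the group).
    """
    j = _joined(intakes, foods, group)
    if len(j) == 0:
        raise ValueError(f"group {group!r} has no retained intake rows")
    n_group = j["individual_id"].nunique()

    # consumption-weighted per-100g profile per category
    w = j["grams_per_day"].to_numpy()[:, None]
    weighted = pd.DataFrame(
        j[PROFILE_COLUMNS].to_numpy() * w, columns=PROFILE_COLUMNS,
        index=j.index,
    )
    weighted["category_id"] = j["category_id"]
    sums = weighted.groupby("category_id").sum()
    grams = j.groupby("category_id")["grams_per_day"].sum()
    per100 = sums.div(grams, axis=0)

    # per-individual daily grams per category (consumers only)
    per_ind = (
        j.groupby(["category_id", "individual_id"])["grams_per_day"]
        .sum()
        .reset_index()
    )
    stats = per_ind.groupby("category_id")["grams_per_day"].agg(
        p10=lambda s: np.percentile(s, 10),
        p75=lambda s: np.percentile(s, 75),
        p90=lambda s: np.percentile(s, 90),
        mean_consumers="mean",
        n_consumers="count",
    )
    stats["mean_all"] = (
        per_ind.groupby("category_id")["grams_per_day"].sum() / n_group
    )

    tax = j.groupby("category_id")[["subgroup_id", "major_group_id"]].first()
    out = pd.concat([tax, per100, stats], axis=1).reset_index()
    return out.sort_values("category_id").reset_index(drop=True)


def consumption_percentiles(
    intakes: pd.DataFrame,
    foods: pd.DataFrame,
    group: str,
    majors_include_zeros: bool = True,
    subtier_include_zeros: bool = False,
) -> pd.DataFrame:
    """Percentile bounds of observed consumption per taxonomy node.

    Major groups get p10 and p90; subgroups and categories get p75.
    Percentiles use linear interpolation between order statistics. At the
    major-group tier, individuals who consumed nothing from the group enter
    as zeros (a population-level bound); at the subgroup/category tier only
    consumers enter, since the bound describes observed consumption amounts.
    Both conventions are switchable.

    Returns a table with columns node_id, tier, p10, p75, p90 (NaN where a
    percentile is not defined for the tier). Nodes consumed by nobody are
    absent.
    """
    j = _joined(intakes, foods, group)
    if len(j) == 0:
        raise ValueError(f"group {group!r} has no retained intake rows")
    n_group = j["individual_id"].nunique()

    rows = []
    for tier, key in (
        ("major", "major_group_id"),
        ("subgroup", "subgroup_id"),
        ("category", "category_id"),
    ):
        per_ind = j.groupby([key, "individual_id"])["grams_per_day"].sum()
        include_zeros = (
            majors_include_zeros if tier == "major" else subtier_include_zeros
        )
        for node, s in per_ind.groupby(level=0):
            vals = s.to_numpy()
            if include_zeros and len(vals) < n_group:
                vals = np.concatenate([vals, np.zeros(n_group - len(vals))])
            row = {"node_id": node, "tier": tier,
                   "p10": np.nan, "p75": np.nan, "p90": np.nan}
            if tier == "major":
                row["p10"] = float(np.percentile(vals, 10))
                row["p90"] = float(np.percentile(vals, 90))
            else:
                row["p75"] = float(np.percentile(vals, 75))
            rows.append(row)
    return pd.DataFrame(rows)


def observed_pattern(
    intakes: pd.DataFrame, categories: pd.DataFrame, group: str
) -> ObservedPattern:
    """The group-mean observed diet over the aggregated categories.

    Amounts are the per-category mean over all retained individuals in the
    group (``mean_all``); totals are the amounts-weighted per-100 g sums.
    """
    if categories is None or len(categories) == 0:
        raise ValueError("empty category list")
    amounts = categories.set_index("category_id")["mean_all"].astype(float)
    totals = pattern_totals(categories, amounts)
    return ObservedPattern(group=group, amounts=amounts, totals=totals)


def pattern_totals(categories: pd.DataFrame, amounts: pd.Series) -> pd.Series:
    """Daily nutrient + MyPyramid totals of a pattern (amounts in g/d)."""
    cat = categories.set_index("category_id")
    a = amounts.reindex(cat.index).fillna(0.0).to_numpy(float)
    return pd.Series(
        a @ cat[PROFILE_COLUMNS].to_numpy(float) / 100.0,
        index=PROFILE_COLUMNS,
    )
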