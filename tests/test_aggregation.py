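"""Filters, category collapse and percentile bounds."""

import numpy as np
import pandas as pd
import pytest

import dietlp as d
from dietlp.nutrients import PROFILE_COLUMNS


def _one_food_table(energy=100.0, excluded="none"):
    from dietlp.synthetic_data import _toy_food
    row = _toy_food("X1", "c.x", "s.x", "vegetables", energy, 10.0, 50.0)
    row["excluded_class"] = excluded
    return pd.DataFrame([row])


def _intake(pid, code, grams, group="M31-50", pregnant=False):
    return (pid, group, pregnant, code, grams)


def _frame(rows):
    return pd.DataFrame(rows, columns=[
        "individual_id", "sex_age_group", "pregnant", "food_code",
        "grams_per_day"])


class TestFilterIndividuals:
    def test_energy_boundary(self):
        """< 600 kcal/d excluded; exactly 600 retained."""
        foods = _one_food_table(energy=100.0)
        intakes = _frame([
            _intake("lo", "X1", 599.0),    # 599 kcal
            _intake("at", "X1", 600.0),    # 600 kcal
            _intake("hi", "X1", 601.0),
        ])
        kept = d.filter_individuals(intakes, foods)
        assert set(kept["individual_id"]) == {"at", "hi"}

    def test_pregnant_and_low_energy_counts(self):
        """10 individuals, 2 pregnant, 1 at 400 kcal/d -> 7 retained."""
        foods = _one_food_table(energy=100.0)
        rows = [_intake(f"p{i}", "X1", 2000.0, group="F31-50",
                        pregnant=i < 2) for i in range(9)]
        rows.append(_intake("p9", "X1", 400.0, group="F31-50"))
        kept = d.filter_individuals(_frame(rows), foods)
        assert kept["individual_id"].nunique() == 7

    def test_unknown_food_code_rejected(self):
        foods = _one_food_table()
        with pytest.raises(ValueError, match="unknown food"):
            d.filter_individuals(_frame([_intake("p", "NOPE", 100.0)]), foods)


class TestFilterFoods:
    @pytest.mark.parametrize("energy,kept", [(9.9, False), (10.0, True)])
    def test_energy_density_boundary(self, energy, kept):
        row = _one_food_table(energy=energy)
        row["excluded_class"] = (
            "low_energy_density" if energy < 10.0 else "none")
        out = d.filter_foods(row)
        assert (len(out) == 1) == kept

    def test_idempotent(self, synth):
        foods, _, _ = synth
        once = d.filter_foods(foods)
        twice = d.filter_foods(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_order_independent_with_individual_filter(self, synth):
        foods, intakes, _ = synth
        a = d.filter_individuals(intakes, foods)
        a = a[a["food_code"].isin(d.filter_foods(foods)["food_code"])]
        b = intakes[intakes["food_code"].isin(
            d.filter_foods(foods)["food_code"])]
        b = d.filter_individuals(b.reset_index(drop=True), foods)
        pd.testing.assert_frame_equal(
            a.sort_values(["individual_id", "food_code"]).reset_index(drop=True),
            b.sort_values(["individual_id", "food_code"]).reset_index(drop=True))


class TestAggregateCategories:
    def test_single_member_identity(self, toy2):
        foods, intakes, profile, cats, *_ = toy2
        f1 = foods.set_index("food_code").loc["F1", PROFILE_COLUMNS]
        c1 = cats.set_index("category_id").loc["c.f1", PROFILE_COLUMNS]
        np.testing.assert_allclose(c1.astype(float), f1.astype(float))

    def test_two_member_weighted_mean(self):
        """Na 100 and 300 mg/100 g consumed 100 g and 300 g -> 250."""
        from dietlp.synthetic_data import _toy_food
        foods = pd.DataFrame([
            _toy_food("A", "c.z", "s.z", "grains", 100.0, 100.0, 10.0),
            _toy_food("B", "c.z", "s.z", "grains", 100.0, 300.0, 10.0),
        ])
        intakes = _frame([_intake("p1", "A", 100.0),
                          _intake("p1", "B", 300.0)])
        cats = d.aggregate_categories(intakes, foods, "M31-50")
        assert cats.loc[0, "sodium_mg"] == pytest.approx(250.0)

    def test_weighted_mean_matches_row_iteration(self, synth_filtered):
        """Brute-force re-aggregation by independent row iteration."""
        foods_f, intakes_f, _ = synth_filtered
        group = "M31-50"
        cats = d.aggregate_categories(intakes_f, foods_f, group)
        j = intakes_f[intakes_f["sex_age_group"] == group].merge(
            foods_f, on="food_code")
        target = cats.set_index("category_id")
        for cat_id in list(target.index)[:15]:
            rows = j[j["category_id"] == cat_id]
            w = rows["grams_per_day"].to_numpy()
            expect = (rows[PROFILE_COLUMNS].to_numpy() * w[:, None]).sum(0) / w.sum()
            np.testing.assert_allclose(
                target.loc[cat_id, PROFILE_COLUMNS].astype(float), expect,
                rtol=1e-9, atol=1e-9)

    def test_mass_conservation(self, synth_filtered):
        """Summing grams x per-100g over raw foods equals summing over
        categories, per nutrient."""
        foods_f, intakes_f, _ = synth_filtered
        group = "F20-30"
        cats = d.aggregate_categories(intakes_f, foods_f, group)
        j = intakes_f[intakes_f["sex_age_group"] == group].merge(
            foods_f, on="food_code")
        raw = (j[PROFILE_COLUMNS].to_numpy()
               * j["grams_per_day"].to_numpy()[:, None]).sum(0)
        grams_per_cat = j.groupby("category_id")["grams_per_day"].sum()
        cat = cats.set_index("category_id")
        agg = (cat.loc[grams_per_cat.index, PROFILE_COLUMNS].to_numpy()
               * grams_per_cat.to_numpy()[:, None]).sum(0)
        np.testing.assert_allclose(agg, raw, rtol=1e-6)

    def test_empty_group_rejected(self, toy2):
        foods, intakes, *_ = toy2
        with pytest.raises(ValueError, match="no retained"):
            d.aggregate_categories(intakes, foods, "F>50")

    def test_stats_ordering(self, synth_group):
        cats, *_ = synth_group
        assert (cats["p10"] <= cats["p75"] + 1e-12).all()
        assert (cats["p75"] <= cats["p90"] + 1e-12).all()
        assert (cats["mean_all"] <= cats["mean_consumers"] + 1e-12).all()


class TestConsumptionPercentiles:
    def test_constant_sample(self):
        foods = _one_food_table()
        rows = [_intake(f"p{i}", "X1", 100.0) for i in range(10)]
        b = d.consumption_percentiles(_frame(rows), foods, "M31-50")
        major = b[b["tier"] == "major"].iloc[0]
        assert major["p10"] == pytest.approx(100.0)
        assert major["p90"] == pytest.approx(100.0)

    def test_linear_interpolation_matches_order_statistics(self):
        """grams {0,10,...,90}: p10/p90 by linear interpolation."""
        foods = _one_food_table()
        rows = [_intake(f"p{i}", "X1", 10.0 * i) for i in range(10)]
        b = d.consumption_percentiles(_frame(rows), foods, "M31-50")
        major = b[b["tier"] == "major"].iloc[0]
        sample = np.arange(0, 100, 10)
        assert major["p10"] == pytest.approx(np.percentile(sample, 10))
        assert major["p90"] == pytest.approx(np.percentile(sample, 90))

    def test_unconsumed_nodes_absent(self, toy2):
        foods, intakes, *_ = toy2
        b = d.consumption_percentiles(intakes, foods, "M31-50")
        assert set(b["node_id"]) == {"vegetables", "grains", "s.f1", "s.f2",
                                     "c.f1", "c.f2"}

    def test_zeros_enter_major_tier(self):
        """An individual consuming nothing from a major group pulls its
        p10 down to zero."""
        from dietlp.synthetic_data import _toy_food
        foods = pd.DataFrame([
            _toy_food("A", "c.a", "s.a", "fruits", 50.0, 5.0, 200.0),
            _toy_food("B", "c.b", "s.b", "grains", 250.0, 400.0, 100.0),
        ])
        rows = [_intake("p1", "A", 100.0), _intake("p1", "B", 100.0),
                _intake("p2", "B", 100.0)]
        b = d.consumption_percentiles(_frame(rows), foods, "M31-50")
        fruit = b[(b["tier"] == "major") & (b["node_id"] == "fruits")].iloc[0]
        # sample over individuals is {0, 100}
        assert fruit["p10"] == pytest.approx(np.percentile([0, 100], 10))
        # consumer-only convention at the category tier
        cat = b[(b["tier"] == "category") & (b["node_id"] == "c.a")].iloc[0]
        assert cat["p75"] == pytest.approx(100.0)


class TestObservedPattern:
    def test_single_row_arithmetic(self):
        foods = _one_food_table(energy=100.0)
        intakes = _frame([_intake("p1", "X1", 200.0)])
        cats = d.aggregate_categories(intakes, foods, "M31-50")
        obs = d.observed_pattern(intakes, cats, "M31-50")
        assert obs.totals["energy_kcal"] == pytest.approx(200.0)

    def test_totals_match_dot_product(self, synth_group):
        cats, _, _, _, obs = synth_group
        cat = cats.set_index("category_id")
        a = obs.amounts.reindex(cat.index).to_numpy()
        expect = a @ cat[PROFILE_COLUMNS].to_numpy() / 100.0
        np.testing.assert_allclose(obs.totals.to_numpy(), expect, rtol=1e-9)

    def test_empty_categories_rejected(self, toy2):
        _, intakes, *_ = toy2
        with pytest.raises(ValueError, match="empty"):
            d.observed_pattern(intakes, pd.DataFrame(), "M31-50")
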