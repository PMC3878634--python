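"""Solver correctness against closed forms and the grid oracle."""

import numpy as np
import pandas as pd
import pytest

import dietlp as d
from dietlp.lp_core import brute_force_optimum

# toy2 closed forms (energy plane 0.5 x1 + 2.5 x2 = 2000 g/d):
#   max K on the r=0.49 line: 451 x2 = 127 x1 and the energy equality give
#   x2 = 5080/1086 (100-g units) -> K* = 12000 - 1400 x2 ~ 5451.2 mg,
#   Na* = 0.49 K* ~ 2671.1 mg.
TOY2_K_STAR = 12000.0 - 1400.0 * (5080.0 / 1086.0)
TOY2_NA_STAR = 0.49 * TOY2_K_STAR


class TestMaxPotassium:
    def test_toy2_with_ratio_closed_form(self, toy2):
        *_, cats, cs, _ = toy2
        sol = d.solve_max_potassium(cats, d.apply_ratio_constraint(cs, 0.49))
        assert sol.status == "optimal"
        assert sol.totals["potassium_mg"] == pytest.approx(TOY2_K_STAR,
                                                           rel=1e-9)
        assert sol.totals["sodium_mg"] == pytest.approx(TOY2_NA_STAR,
                                                        rel=1e-9)

    def test_toy2_energy_only_endpoint(self, toy2):
        """Without the ratio, max K sits at the x2 = 0 endpoint."""
        *_, cats, cs, _ = toy2
        sol = d.solve_max_potassium(cats, cs)
        assert sol.objective_value == pytest.approx(12000.0, rel=1e-9)
        assert sol.amounts["c.f1"] == pytest.approx(4000.0, rel=1e-9)

    def test_single_category_forced(self):
        from dietlp.synthetic_data import _toy_food
        foods = pd.DataFrame(
            [_toy_food("A", "c.a", "s.a", "fruits", 100.0, 10.0, 250.0)])
        intakes = pd.DataFrame(
            [("p1", "M31-50", False, "A", 100.0)],
            columns=["individual_id", "sex_age_group", "pregnant",
                     "food_code", "grams_per_day"])
        cats = d.aggregate_categories(intakes, foods, "M31-50")
        prof = d.GroupProfile(group="M31-50", eer_kcal=1000.0,
                              dri=pd.DataFrame(
                                  columns=["nutrient", "min", "max"]))
        sol = d.solve_max_potassium(cats, d.build_constraint_set(prof))
        assert sol.amounts["c.a"] == pytest.approx(1000.0, rel=1e-9)
        assert sol.totals["potassium_mg"] == pytest.approx(2500.0, rel=1e-9)

    def test_unbounded_flagged(self):
        """A zero-energy food under an energy equality it cannot affect
        leaves potassium unbounded above only if energy can be met; with a
        degenerate zero-energy single food the model is infeasible, never
        silently 'optimal'."""
        from dietlp.synthetic_data import _toy_food
        foods = pd.DataFrame(
            [_toy_food("Z", "c.z", "s.z", "beverages", 0.0, 0.0, 100.0)])
        intakes = pd.DataFrame(
            [("p1", "M31-50", False, "Z", 100.0)],
            columns=["individual_id", "sex_age_group", "pregnant",
                     "food_code", "grams_per_day"])
        cats = d.aggregate_categories(intakes, foods, "M31-50")
        prof = d.GroupProfile(group="M31-50", eer_kcal=2000.0,
                              dri=pd.DataFrame(
                                  columns=["nutrient", "min", "max"]))
        sol = d.solve_max_potassium(cats, d.build_constraint_set(prof))
        assert sol.status == "infeasible"


class TestMinDeviation:
    def test_feasible_incumbent_is_optimal(self, toy2):
        """The observed toy2 pattern satisfies the energy-only set, so the
        deviation optimum is the observed diet itself with score 0."""
        *_, cats, cs, obs = toy2
        sol = d.solve_min_deviation(cats, cs, obs)
        assert sol.deviation_score == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(
            sol.amounts.reindex(obs.amounts.index), obs.amounts, atol=1e-6)

    def test_zero_score_implies_observed_feasible(self, synth_group):
        """Converse direction: a zero deviation score certifies that the
        observed pattern satisfies the constraint set (checked by direct
        substitution into the matrices)."""
        import pandas as pd
        cats, _, profile, _, obs = synth_group
        # energy equality at the observed energy (and no DRI rows, which
        # observed diets genuinely fall short of) makes the incumbent valid
        prof = d.GroupProfile(group=profile.group,
                              eer_kcal=float(obs.totals["energy_kcal"]),
                              dri=pd.DataFrame(
                                  columns=["nutrient", "min", "max"]))
        cs = d.build_constraint_set(prof)
        sol = d.solve_min_deviation(cats, cs, obs)
        assert sol.deviation_score == pytest.approx(0.0, abs=1e-8)
        p = d.to_lp_problem(cats, cs)
        x = obs.amounts.reindex(p.variables).to_numpy()
        assert np.abs(p.A_eq @ x - p.b_eq).max() <= 1e-6 * np.abs(
            p.b_eq).max()
        if p.b_ub.size:
            assert ((p.A_ub @ x - p.b_ub)
                    <= 1e-6 * np.maximum(np.abs(p.b_ub), 1)).all()

    def test_projection_onto_ratio_line(self, toy2):
        """With the r=0.49 equality added, the optimum is the projection of
        the observed diet onto the (single-point) feasible set, and the
        score equals the weighted L1 distance."""
        *_, cats, cs, obs = toy2
        sol = d.solve_min_deviation(
            cats, d.apply_ratio_constraint(cs, 0.49), obs)
        w = d.lp_core.deviation_weights(obs)
        expect = float(
            (w * (sol.amounts.reindex(obs.amounts.index)
                  - obs.amounts).abs()).sum())
        assert sol.deviation_score == pytest.approx(expect, rel=1e-9)
        # the feasible set here is one point: energy + ratio pin it down
        assert sol.totals["potassium_mg"] == pytest.approx(TOY2_K_STAR,
                                                           rel=1e-6)

    def test_infeasible_reported(self, toy2):
        *_, cats, cs, obs = toy2
        sol = d.solve_min_deviation(cats, d.fix_sodium(cs, 0.0), obs)
        assert sol.status == "infeasible"
        assert sol.amounts is None


class TestBruteForceOracle:
    def test_max_k_agreement_toy2(self, toy2):
        *_, cats, cs, _ = toy2
        csr = d.apply_ratio_constraint(cs, 0.49)
        sol = d.solve_max_potassium(cats, csr)
        st, val, x = brute_force_optimum(cats, csr, "max_potassium",
                                         grid_step=0.01)
        assert st == "optimal"
        assert val == pytest.approx(sol.objective_value, rel=0.01)

    def test_min_deviation_agreement_toy3(self, toy3):
        *_, cats, cs, obs = toy3
        csr = d.apply_ratio_constraint(cs, 0.49)
        sol = d.solve_min_deviation(cats, csr, obs)
        st, val, x = brute_force_optimum(cats, csr, "min_deviation",
                                         grid_step=0.01, observed=obs)
        assert st == "optimal"
        assert val == pytest.approx(sol.deviation_score, rel=0.01, abs=1e-4)

    def test_infeasible_grid_reported(self, toy2):
        *_, cats, cs, _ = toy2
        st, val, x = brute_force_optimum(cats, d.fix_sodium(cs, 0.0),
                                         "max_potassium", grid_step=1.0)
        assert st == "infeasible"
        assert x is None

    def test_constant_objective(self, toy2):
        """All-zero potassium makes any feasible point optimal at 0."""
        *_, cats, cs, _ = toy2
        cats0 = cats.copy()
        cats0["potassium_mg"] = 0.0
        st, val, _ = brute_force_optimum(cats0, cs, "max_potassium",
                                         grid_step=1.0)
        assert st == "optimal"
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_rejects_large_instances(self, synth_group):
        cats, cs = synth_group[0], synth_group[3]
        with pytest.raises(ValueError, match="3 categories"):
            brute_force_optimum(cats, cs, "max_potassium")


class TestSolutionProperties:
    def test_scale_invariance(self, toy2):
        """Scaling per-100 g vectors by c rescales amounts by 1/c but
        leaves nutrient totals and the objective unchanged."""
        *_, cats, cs, _ = toy2
        c = 4.0
        scaled = cats.copy()
        from dietlp.nutrients import PROFILE_COLUMNS
        scaled[PROFILE_COLUMNS] = scaled[PROFILE_COLUMNS] * c
        sol = d.solve_max_potassium(cats, d.apply_ratio_constraint(cs, 0.49))
        sol_c = d.solve_max_potassium(scaled,
                                      d.apply_ratio_constraint(cs, 0.49))
        assert sol_c.objective_value == pytest.approx(sol.objective_value,
                                                      rel=1e-9)
        np.testing.assert_allclose(sol_c.amounts * c, sol.amounts, rtol=1e-6)

    def test_run_to_run_reproducibility(self, synth_group):
        cats, _, _, cs, _ = synth_group
        a = d.solve_max_potassium(cats, d.apply_ratio_constraint(cs, 0.49))
        b = d.solve_max_potassium(cats, d.apply_ratio_constraint(cs, 0.49))
        np.testing.assert_array_equal(a.amounts.to_numpy(),
                                      b.amounts.to_numpy())

    def test_json_serialization(self, toy2, tmp_path):
        import json
        *_, cats, cs, _ = toy2
        sol = d.solve_max_potassium(cats, cs)
        sol.to_json(tmp_path / "sol.json")
        back = json.loads((tmp_path / "sol.json").read_text())
        assert back["status"] == "optimal"
        assert back["amounts"]["c.f1"] == pytest.approx(4000.0)
        assert "energy" in back["binding"]
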