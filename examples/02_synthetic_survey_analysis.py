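"""Full single-group analysis on a seeded synthetic intake survey.

Generates a 120-category food database and a six-group one-day survey,
applies the exclusion filters, collapses foods into consumption-weighted
categories, builds the constraint system (energy equality at the group EER,
DRI rows, percentile consumption bounds), then maps the feasible (Na, K)
region and finds the nutritionally adequate pattern closest to observed
eating habits at the guideline Na:K ratio of 0.49.
"""

import dietlp as d

spec = d.TaxonomySpec(n_categories=120)
foods = d.generate_food_database(n_foods=300, taxonomy_spec=spec, seed=3)
intakes, profiles = d.generate_intake_survey(
    foods, dict.fromkeys(d.SEX_AGE_GROUPS, 80), seed=3)

foods_f = d.filter_foods(foods)
intakes_f = d.filter_individuals(intakes, foods, verbose=True)

group = "M20-30"
cats = d.aggregate_categories(intakes_f, foods_f, group)
bounds = d.consumption_percentiles(intakes_f, foods_f, group)
profile = next(p for p in profiles if p.group == group)
cs = d.build_constraint_set(profile, bounds, vitamin_e_override=True)
print(f"{group}: {len(cats)} food categories, EER {profile.eer_kcal:.0f} "
      f"kcal/d")

na, k, _ = d.max_k_at_ratio(cats, cs, r=0.49)
print(f"max K on the 0.49 ratio line: Na = {na / 1000:.2f} g/d, "
      f"K = {k / 1000:.2f} g/d")

region = d.sweep_sodium(cats, cs, start_mg=na, step_mg=100.0)
lo, hi = region.na_interval
print(f"feasible sodium interval: [{lo / 1000:.2f}, {hi / 1000:.2f}] g/d")
for limit in (2300.0, 1500.0):
    ok, wit = d.check_guideline_compatibility(region, limit, 4700.0)
    print(f"  Na <= {limit:.0f} mg with K >= 4700 mg: "
          f"{'attainable' if ok else 'NOT attainable'}")

obs = d.observed_pattern(intakes_f, cats, group)
mindev = d.solve_min_deviation(cats, d.apply_ratio_constraint(cs, 0.49), obs)
print(f"\nminimum-deviation pattern at Na:K = 0.49: "
      f"Na = {mindev.totals['sodium_mg'] / 1000:.2f} g/d, "
      f"K = {mindev.totals['potassium_mg'] / 1000:.2f} g/d")
print("\nobserved vs optimized food pattern (MyPyramid units):")
print(d.compare_patterns(obs, mindev).table.round(2).to_string(index=False))
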