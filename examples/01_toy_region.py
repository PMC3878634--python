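"""Map the (sodium, potassium) feasibility region of a two-food diet.

The toy2 fixture has two foods per 100 g — F1: 50 kcal, 20 mg Na, 300 mg K;
F2: 250 kcal, 500 mg Na, 100 mg K — and a 2000 kcal/d energy equality.
Every feasible diet lies on a line segment, so the region has a closed form
we can print next to the sweep output: Na runs over [800, 4000] mg/d and
K = 12000 - 3.5 (Na - 800).
"""

import dietlp as d

foods, intakes, profile = d.make_toy_fixture("toy2")
cats = d.aggregate_categories(intakes, foods, profile.group)
cs = d.build_constraint_set(profile)

na, k, _ = d.max_k_at_ratio(cats, cs, r=0.49)
print(f"K-maximal point on the Na:K = 0.49 line: "
      f"Na = {na:.1f} mg/d, K = {k:.1f} mg/d")

region = d.sweep_sodium(cats, cs, start_mg=4000.0, step_mg=100.0)
lo, hi = region.na_interval
print(f"feasible sodium interval: [{lo:.0f}, {hi:.0f}] mg/d "
      f"(closed form: [800, 4000])")

f = region.feasible_grid()
for _, row in f[f.sodium_mg.isin([800.0, 2300.0, 4000.0])].iterrows():
    pred = 12000.0 - 3.5 * (row.sodium_mg - 800.0)
    print(f"  Na = {row.sodium_mg:6.0f} mg/d -> K = {row.k_max_mg:8.1f} mg/d"
          f"   (closed form {pred:8.1f})")

ok, wit = d.check_guideline_compatibility(region, na_limit=2300.0,
                                          k_goal=4700.0)
print(f"Na <= 2300 with K >= 4700 jointly attainable: {ok}; "
      f"witness (Na, K) = {wit}")
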