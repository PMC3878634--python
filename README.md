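# dietlp

Linear-programming food pattern modeling for the sodium–potassium problem:
can a diet meet a sodium upper limit (2300 mg/d, or the stricter 1500 mg/d)
and the potassium goal (4700 mg/d) at the same time while staying
nutritionally adequate and close to what people actually eat?

`dietlp` is a library for building and solving these diet LPs from an
intake survey joined to a food-composition table. It is aimed at nutrition
modelers and epidemiologists who want to reason about guideline feasibility
rather than individual meal plans.

## The model

For one sex–age group, each consumed food category *i* is a continuous
variable *x<sub>i</sub>* ≥ 0 (g/d) with a per-100 g nutrient profile
obtained as the consumption-weighted mean of its member foods. The
constraint system is

- **energy equality** — Σ e<sub>i</sub> x<sub>i</sub> = EER, the group's
  estimated energy requirement;
- **nutrient adequacy** — one row per DRI entry,
  Σ a<sub>i</sub> x<sub>i</sub> ≥ min or ≤ max;
- **consumption habits** — each of the 9 major food groups bounded by the
  10th and 90th percentiles of observed consumption; each subgroup and
  category capped at its 75th percentile;
- optionally the **Na:K mass-ratio equality** Na − r·K = 0 with
  r = 2300/4700 ≈ 0.49, or a **fixed-sodium equality** Na = s.

Two objectives are solved (HiGHS via `scipy.optimize.linprog`):

1. **max K** — maximize Σ k<sub>i</sub> x<sub>i</sub>, first on the ratio
   line, then with the ratio removed while the fixed sodium level *s* is
   stepped down/up in 0.1 g increments until infeasible. The resulting
   (Na, [K<sub>min</sub>, K<sub>max</sub>]) grid is the 2-D projection of
   the diet polytope — the *feasibility region*.
2. **min deviation** — minimize Σ w<sub>i</sub> |x<sub>i</sub> −
   obs<sub>i</sub>| (weighted L1, linearized with split variables), the
   nutritionally adequate pattern closest to observed eating habits.

A food-supply scenario scales every food's sodium by a multiplier
(default 0.90); this maps the region exactly via (Na, K) → (0.9 Na, K).

Because no survey microdata are shipped, a seeded synthetic generator
(`dietlp.synthetic_data`) emulates the structure such an analysis needs:
six sex–age groups, a 3-tier taxonomy under 9 major food groups,
right-skewed consumption, sodium concentrated in grain/mixed/prepared
foods and potassium in fruits, vegetables and dairy. Tiny hand-solvable
fixtures (`make_toy_fixture`) back every solver against closed forms.

## Worked example

```bash
python examples/01_toy_region.py
```

```
K-maximal point on the Na:K = 0.49 line: Na = 2671.1 mg/d, K = 5451.2 mg/d
feasible sodium interval: [800, 4000] mg/d (closed form: [800, 4000])
  Na =    800 mg/d -> K =  12000.0 mg/d   (closed form  12000.0)
  Na =   2300 mg/d -> K =   6750.0 mg/d   (closed form   6750.0)
  Na =   4000 mg/d -> K =    800.0 mg/d   (closed form    800.0)
Na <= 2300 with K >= 4700 jointly attainable: True; witness (Na, K) = (2300.0, 6750.0)
```

With two foods and an energy equality the diet space is a segment, so the
region is a line: the sweep reproduces K = 12000 − 3.5 (Na − 800) exactly,
and the guideline query returns the best potassium available at the
2300 mg sodium line.

`examples/02_synthetic_survey_analysis.py` runs the full pipeline on a
synthetic survey (120 categories, EER 2800 kcal/d group): it prints the
feasible sodium interval, guideline verdicts, the minimum-deviation
pattern at the 0.49 ratio (≈ 2.3 g Na, 4.8 g K per day), and an
observed-vs-optimized MyPyramid table — the optimized pattern carries more
fruits, vegetables and milk and fewer refined grains and meats.
`examples/03_sodium_reduction.py` shows the 10% sodium-cut scenario
relocating the region without reshaping attainable potassium. A thin CLI
(`dietlp generate | aggregate | run`) wraps the same pipeline.

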