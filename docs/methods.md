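# Methods

## Problem and model

The package answers feasibility questions about dietary guidelines for one
sex–age group at a time. The decision variables are daily amounts (grams)
of the food *categories* the group actually consumes; every nutrient is
linear in those amounts, so each question is a linear program over the
polytope cut out by:

- an energy **equality** at the group's estimated energy requirement
  (EER). We treat this as a strict equality (solver tolerance 1e-6
  relative): diets are compared at fixed energy, otherwise "more
  potassium" is trivially available by eating more of everything.
- DRI nutrient rows (≥ minimum and/or ≤ maximum, native units per day).
- consumption bounds from the observed distributions: [p10, p90] for each
  of the 9 major food groups, [0, p75] for subgroups and categories.
  These keep optimized patterns inside the envelope of real eating habits.
- optionally the Na:K mass-ratio equality Na − r·K = 0 (r = 2300/4700 by
  default) or a fixed-sodium equality. The ratio is implemented as an
  equality because the analysis pins the guideline-implied ratio and asks
  what (Na, K) levels are then attainable; an inequality variant can be
  expressed by adding a sodium `<=` row instead.

All variables are continuous with lower bound 0 — amounts of composite
food categories, not servings, so integrality would be meaningless.

The sodium/potassium guideline rows themselves are *not* part of the
default DRI table: the feasibility sweep replaces them (a fixed-sodium
equality while sodium is stepped), and leaving a sodium cap active during
a sweep would silently truncate the region. They can be toggled on for
experiments that need them.

## Feasibility region

The 2-D projection of the polytope onto (Na, K) is mapped by anchoring at
the K-maximal point on the ratio line, dropping the ratio, and stepping a
fixed-sodium equality down (and up) in 100 mg = 0.1 g increments until the
LP first reports infeasibility. At each feasible level both a max-K and a
min-K LP are solved. Only the upper envelope is needed for guideline
verdicts; the min-K LP is a reconstruction that closes the region so it
can be plotted and queried as a 2-D set. Convexity of the projection
guarantees the feasible sodium levels form an interval, the K upper
envelope is concave and the lower one convex — the property tests assert
all three at grid resolution. If the starting level is infeasible the
sweep searches upward (bounded by the polytope's own maximum sodium from a
max-Na LP) for the first feasible level before sweeping.

`region_contains` interpolates the envelopes linearly between grid points;
`check_guideline_compatibility(region, na_limit, k_goal)` reports whether
some feasible grid level has Na ≤ limit and K<sub>max</sub> ≥ goal, with
the witness taken at the largest qualifying sodium level.

## Deviation functional

"Closest to existing habits" is the weighted L1 distance
Σ w<sub>i</sub> |x<sub>i</sub> − obs<sub>i</sub>| with obs the group-mean
observed diet and w<sub>i</sub> = 1/obs<sub>i</sub> (so a 10 g change in a
20 g/d habit counts like a 100 g change in a 200 g/d habit). Categories
with zero observed mean fall back to 1/(mean positive portion). A plain L1
(`weighting="uniform"`) is available. The functional is linearized with
split variables x − obs = d⁺ − d⁻, d<sup>±</sup> ≥ 0, objective
Σ w (d⁺ + d⁻); the reported score is recomputed from the returned amounts,
not read off the auxiliary variables. Zero score is equivalent to the
observed pattern satisfying the constraint set, which the tests check in
both directions.

## Solver and numerics

All LPs go through `scipy.optimize.linprog` (HiGHS), deterministic under
fixed inputs; solutions are additionally verified against the constraint
matrices at 1e-6 relative before being accepted, and binding rows are
reported via the row-provenance labels. Alternative optima are possible in
principle; where determinism across runs is what matters the deterministic
solver settings suffice (asserted by the reproducibility tests). A
lexicographic refinement (re-solving with the objective pinned) can be
layered on by callers that need a canonical vertex, at the cost of one
extra solve per variable; the default path does not pay that cost.

The brute-force oracle re-solves ≤ 3-variable instances without LP
machinery: the last variable is eliminated through the energy equality and
the remaining box is grid-scanned. With one free variable the scan is
exhaustive at the requested step; with two, an exhaustive coarse scan
(≤ 1500 points per axis) is refined ×4 around the incumbent until the cell
size reaches the requested step. Feasibility on the grid uses a tolerance
of step × Σ|a<sub>row</sub>| per row, so thin sets (equality lines) remain
visible at every scale and the scan converges to the LP optimum as the
step → 0. Fixture agreement with the LP solver is asserted at 1%.

## Synthetic data

The generator provides the statistical *shape* the pipeline needs, not a
re-creation of any real survey:

- **taxonomy**: 9 major groups, 39 subgroups, a configurable number of
  categories (default 100, range of interest roughly 85–130; the count is
  a parameter, reflecting that group-specific variable lists vary).
- **composition**: per-major-group log-normal templates (median, log-sd
  0.45; 1.2 for beverages) — positive and right-skewed like real
  composition data. Medians encode the gradient the analysis exploits:
  fruits/vegetables ≈ 220–280 mg K and 4–45 mg Na per 100 g versus
  grains/mixed dishes ≈ 120–180 mg K and 420–450 mg Na. Macronutrients are
  drawn as energy shares so protein/fat/carbohydrate stay consistent with
  energy; SoFAS kcal is 9·solid fat + 4·added sugar by construction.
- **intakes**: one day per individual (matching the single-day recall
  structure such surveys often have), 20–60 distinct foods, log-normal
  gram amounts scaled to an energy target ~Normal(EER, 0.18·EER). Default
  EERs: 2800/2600/2000 kcal/d for men 20–30/31–50/>50 and 2200/2000/1800
  for women. 2% of women are generated pregnant and 2% of individuals
  report < 600 kcal/d, to exercise the exclusion filters.
- **DRI defaults** are a documented synthetic table (protein 50 g, fiber
  18 g, calcium 800 mg, magnesium 260 mg, zinc 8 mg, iron 8 mg, vitamins
  A/C/E 500 µg/55 mg/9 mg, folate 300 µg) — configuration entries chosen
  to be binding-but-satisfiable in this synthetic world, not claims about
  real DRIs. The vitamin E minimum is reset to 13 mg/d for the young-men
  group when the override is requested, mirroring the convention of
  assuming a tablespoon of vegetable oil for a group that reports none.

What the generator does **not** emulate: survey weights, day-to-day
variance, item-level FNDDS codes, regional or seasonal structure,
correlation between nutrient densities beyond the major-group templates.
Tests passing on this world show the *machinery* is correct (filters,
aggregation identities, LP geometry, scenario algebra); they do not certify
numeric conclusions about any real population.

## Aggregation conventions

- "Frequency-of-occurrence" weights are total grams consumed of each food
  within the group. This conserves mass-weighted nutrient totals exactly
  (asserted at 1e-6 relative) and is well defined with one intake day.
- Percentiles use linear interpolation between order statistics
  (`numpy.percentile` default), documented so the test oracle matches.
  Major-group percentiles include non-consumers as zeros (a population
  bound); subgroup/category p75 is over consumers only (a bound on
  observed consumption amounts). Both are switchable.
- The individual-level energy screen (< 600 kcal/d) is computed against
  the unfiltered foods table, so exclusions reflect everything a person
  reported; food- and individual-level filters commute (tested).

## Scenario algebra

Scaling every food's sodium by m maps any diet's sodium total by m and
changes nothing else, so the feasibility region maps exactly via
(Na, K) → (m·Na, K). Sweeping the scaled system on the scaled grid
(start m·s, step m·Δ) makes the correspondence exact point-by-point, which
the tests assert to 1e-6; it also implies the qualitative conclusion that
an across-the-board cut relocates the attainable sodium range without
creating new potassium headroom.

## Problem sizes

The shipped analyses use 120 food categories, 80 individuals per group and
100 mg sweep steps — enough for every structural property (region
geometry, scenario algebra, direction of the energy-level findings) to be
exercised at desk scale. All sizes are parameters.

## Known limitations

- Composite categories average over member foods; a finer variable list
  could enlarge feasibility regions somewhat.
- The region's lower K envelope is a modeling reconstruction (min-K LP),
  not something guideline verdicts depend on.
- Group-level means hide within-group variance; the LP yields one pattern
  per group, with no distributional statement.
- The deviation functional is one defensible choice among several; rank
  orderings of "closeness" can differ under other norms.
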