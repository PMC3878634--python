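"""Feasible (sodium, potassium) region of a constraint set.

The region is the 2-D projection of the diet polytope onto daily sodium and
potassium.  Its upper-right anchor is the potassium-maximal point on the
Na:K guideline-ratio line; the full region is mapped by removing the ratio
constraint and sweeping a fixed-sodium equality downward (and upward) in
0.1 g steps, solving a max-K and a min-K LP at each level until the model
turns infeasible.  Because the projection of a polytope is convex, the
feasible sodium levels form an interval and the K envelopes are
concave/convex, which the property tests exploit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constraints import ConstraintSet, drop_ratio_constraint, fix_sodium
from .lp_core import (
    FEAS_RTOL,
    INFEASIBLE,
    OPTIMAL,
    LPSolution,
    solve_extreme_sodium,
    solve_max_potassium,
    solve_min_potassium,
)
from .nutrients import DEFAULT_NA_K_RATIO, POTASSIUM, SODIUM

#: Default sweep step: 0.1 g of sodium.
DEFAULT_STEP_MG = 100.0


@dataclass
class FeasibilityRegion:
    group: str
    scenario: str
    grid: pd.DataFrame          # sodium_mg, k_min_mg, k_max_mg, feasible
    step: float
    na_interval: tuple = (np.nan, np.nan)   # [na_lo, na_hi] mg/d, grid-based

    def __post_init__(self):
        g = self.grid
        if len(g) and g["feasible"].any():
            feas = g.loc[g["feasible"], "sodium_mg"]
            self.na_interval = (float(feas.min()), float(feas.max()))

    @property
    def empty(self) -> bool:
        return len(self.grid) == 0 or not self.grid["feasible"].any()

    def feasible_grid(self) -> pd.DataFrame:
        return self.grid[self.grid["feasible"]].reset_index(drop=True)

    def max_potassium(self) -> float:
        return float(self.feasible_grid()["k_max_mg"].max())

    # -- export -----------------------------------------------------------
    def to_csv(self, path) -> None:
        self.grid.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        d = {
            "group": self.group,
            "scenario": self.scenario,
            "step_mg": self.step,
            "na_interval_mg": [self.na_interval[0], self.na_interval[1]],
            "n_grid": int(len(self.grid)),
            "n_feasible": int(self.grid["feasible"].sum()) if len(self.grid)
            else 0,
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def max_k_at_ratio(
    categories: pd.DataFrame,
    cs: ConstraintSet,
    r: float = DEFAULT_NA_K_RATIO,
) -> tuple[float, float, LPSolution]:
    """Potassium-maximal point on the Na:K ratio line.

    Returns ``(Na*, K*, solution)`` with ``Na* = r * K*`` within tolerance;
    on infeasibility the coordinates are NaN and the solution carries the
    status.
    """
    if cs.fixed_sodium_mg is not None:
        raise ValueError("constraint set already fixes sodium")
    from .constraints import apply_ratio_constraint

    sol = solve_max_potassium(categories, apply_ratio_constraint(cs, r))
    if sol.status != OPTIMAL:
        return float("nan"), float("nan"), sol
    return float(sol.totals[SODIUM]), float(sol.totals[POTASSIUM]), sol


def _k_bounds_at(categories, base_cs, na_mg):
    cs = fix_sodium(base_cs, na_mg)
    hi = solve_max_potassium(categories, cs)
    if hi.status != OPTIMAL:
        return None
    lo = solve_min_potassium(categories, cs)
    return float(lo.totals[POTASSIUM]), float(hi.totals[POTASSIUM])


def sweep_sodium(
    categories: pd.DataFrame,
    cs: ConstraintSet,
    start_mg: float,
    step_mg: float = DEFAULT_STEP_MG,
    max_levels: int = 10000,
    group: str | None = None,
    scenario: str = "baseline",
) -> FeasibilityRegion:
    """Map the feasible region by stepping a fixed-sodium equality.

    From ``start_mg`` the sodium level is decreased by ``step_mg`` until the
    model first turns infeasible, then swept upward from the start the same
    way, so the grid records both boundaries.  Any ratio constraint on
    ``cs`` is removed first (the sweep protocol replaces it).  At each
    feasible level both the max-K and min-K LPs are solved.

    If the start level itself is infeasible, the first feasible level above
    it is searched for before sweeping; if none exists below the
    polytope-wide maximum sodium, an empty region is returned.
    """
    if start_mg < 0:
        raise ValueError("start_mg must be non-negative")
    if step_mg <= 0:
        raise ValueError("step_mg must be positive")
    base = drop_ratio_constraint(cs)  # fix_sodium below overrides any level
    group = group or cs.group

    rows = []

    def record(na, kb):
        if kb is None:
            rows.append((na, np.nan, np.nan, False))
            return False
        rows.append((na, kb[0], kb[1], True))
        return True

    start = float(start_mg)
    if _k_bounds_at(categories, base, start) is None:
        # search upward for the first feasible level, capped by the
        # polytope's own maximum sodium
        cap_sol = solve_extreme_sodium(categories, base, maximize=True)
        if cap_sol.status != OPTIMAL:
            return FeasibilityRegion(group, scenario,
                                     _grid_frame(rows), step_mg)
        cap = float(cap_sol.totals[SODIUM])
        na = start
        found = None
        while na <= cap + step_mg and len(rows) < max_levels:
            kb = _k_bounds_at(categories, base, na)
            if kb is not None:
                found = na
                break
            na += step_mg
        if found is None:
            return FeasibilityRegion(group, scenario,
                                     _grid_frame(rows), step_mg)
        start = found

    # downward sweep (records the start level too)
    na = start
    for _ in range(max_levels):
        if not record(na, _k_bounds_at(categories, base, na)):
            break
        na -= step_mg
        if na < -step_mg / 2:
            break
    # upward sweep
    na = start + step_mg
    for _ in range(max_levels):
        if not record(na, _k_bounds_at(categories, base, na)):
            break
        na += step_mg

    return FeasibilityRegion(group, scenario, _grid_frame(rows), step_mg)


def _grid_frame(rows) -> pd.DataFrame:
    g = pd.DataFrame(rows,
                     columns=["sodium_mg", "k_min_mg", "k_max_mg", "feasible"])
    return g.sort_values("sodium_mg").reset_index(drop=True)


def region_contains(region: FeasibilityRegion, na: float, k: float) -> bool:
    """Whether (na, k) mg/d lies in the region, interpolating the K
    envelopes linearly between grid points."""
    if region.empty:
        raise ValueError("empty region")
    lo, hi = region.na_interval
    if not (lo - FEAS_RTOL <= na <= hi + FEAS_RTOL):
        return False
    f = region.feasible_grid()
    kmin = float(np.interp(na, f["sodium_mg"], f["k_min_mg"]))
    kmax = float(np.interp(na, f["sodium_mg"], f["k_max_mg"]))
    tol = FEAS_RTOL * max(abs(k), 1.0)
    return kmin - tol <= k <= kmax + tol


def check_guideline_compatibility(
    region: FeasibilityRegion, na_limit: float, k_goal: float
) -> tuple[bool, tuple | None]:
    """Can the diet meet ``Na <= na_limit`` and ``K >= k_goal`` jointly?

    True iff some feasible grid point has sodium at or below the limit and
    an upper potassium envelope reaching the goal.  Returns the witness
    (Na, k_max) at the largest qualifying sodium level, or None.
    """
    if region.empty:
        raise ValueError("empty region")
    f = region.feasible_grid()
    ok = f[(f["sodium_mg"] <= na_limit + FEAS_RTOL)
           & (f["k_max_mg"] >= k_goal - FEAS_RTOL)]
    if len(ok) == 0:
        return False, None
    row = ok.loc[ok["sodium_mg"].idxmax()]
    return True, (float(row["sodium_mg"]), float(row["k_max_mg"]))


def plot_region(region: FeasibilityRegion, ax=None, **kwargs):
    """Render the region as a filled band over the sodium grid (requires
    matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    f = region.feasible_grid()
    ax.fill_between(f["sodium_mg"] / 1000.0, f["k_min_mg"] / 1000.0,
                    f["k_max_mg"] / 1000.0, alpha=0.4, **kwargs)
    ax.set_xlabel("sodium (g/d)")
    ax.set_ylabel("potassium (g/d)")
    ax.set_title(f"{region.group} — {region.scenario}")
    return ax
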