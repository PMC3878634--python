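"""LP solvers for the two diet-optimization objectives, plus a grid oracle.

Two objectives are supported: maximize total daily potassium, and minimize
the (weighted L1) deviation of the pattern from the observed group-mean
diet.  Problems are solved with the HiGHS simplex/IPM backend through
``scipy.optimize.linprog`` with deterministic settings.  A brute-force grid
scanner over instances with at most three variables serves as an
independent oracle for the analytic fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .aggregation import ObservedPattern, pattern_totals
from .constraints import ConstraintSet, LPProblem, to_lp_problem
from .nutrients import ENERGY, POTASSIUM, PROFILE_COLUMNS, SODIUM

#: Shared relative feasibility tolerance (also used by the region mapper).
FEAS_RTOL = 1e-6

OPTIMAL, INFEASIBLE, UNBOUNDED = "optimal", "infeasible", "unbounded"


@dataclass
class LPSolution:
    status: str                     # optimal | infeasible | unbounded
    amounts: pd.Series | None       # category_id -> g/d
    objective_value: float | None
    totals: pd.Series | None        # nutrient + pyramid daily totals
    deviation_score: float | None = None
    binding: list | None = None     # provenance labels of binding rows

    def to_json(self, path=None) -> str:
        d = {
            "status": self.status,
            "amounts": None if self.amounts is None else
            {k: float(v) for k, v in self.amounts.items()},
            "objective_value": self.objective_value,
            "totals": None if self.totals is None else
            {k: float(v) for k, v in self.totals.items()},
            "deviation_score": self.deviation_score,
            "binding": self.binding,
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _statuses(res) -> str:
    # scipy/HiGHS status codes: 0 optimal, 2 infeasible, 3 unbounded
    if res.status == 0:
        return OPTIMAL
    if res.status == 3:
        return UNBOUNDED
    return INFEASIBLE


def _check_feasible(problem: LPProblem, x: np.ndarray) -> None:
    scale_eq = np.maximum(np.abs(problem.b_eq), 1.0)
    resid = np.abs(problem.A_eq @ x - problem.b_eq) / scale_eq
    if resid.size and resid.max() > 1e3 * FEAS_RTOL:
        raise RuntimeError(
            f"solver returned optimal but equality residual {resid.max():.2e}"
        )
    if problem.b_ub.size:
        scale_ub = np.maximum(np.abs(problem.b_ub), 1.0)
        viol = (problem.A_ub @ x - problem.b_ub) / scale_ub
        if viol.max() > 1e3 * FEAS_RTOL:
            raise RuntimeError(
                f"solver returned optimal but inequality violated "
                f"{viol.max():.2e}"
            )


def _binding_rows(problem: LPProblem, x: np.ndarray) -> list:
    out = list(problem.eq_labels)
    if problem.b_ub.size:
        scale = np.maximum(np.abs(problem.b_ub), 1.0)
        slack = (problem.b_ub - problem.A_ub @ x) / scale
        out += [lab for lab, s in zip(problem.ub_labels, slack)
                if s <= 10 * FEAS_RTOL]
    return out


def _solve(problem: LPProblem, c: np.ndarray):
    return linprog(
        c,
        A_ub=problem.A_ub if problem.b_ub.size else None,
        b_ub=problem.b_ub if problem.b_ub.size else None,
        A_eq=problem.A_eq, b_eq=problem.b_eq,
        bounds=(0, None), method="highs",
    )


def _solution_from(categories: pd.DataFrame, problem: LPProblem, res,
                   objective_value=None, deviation=None) -> LPSolution:
    status = _statuses(res)
    if status != OPTIMAL:
        return LPSolution(status=status, amounts=None, objective_value=None,
                          totals=None)
    x = res.x[: len(problem.variables)]
    x = np.maximum(x, 0.0)
    _check_feasible(problem, x)
    amounts = pd.Series(x, index=problem.variables, name="g_per_day")
    totals = pattern_totals(categories, amounts)
    return LPSolution(
        status=OPTIMAL, amounts=amounts,
        objective_value=float(res.fun if objective_value is None
                              else objective_value),
        totals=totals, deviation_score=deviation,
        binding=_binding_rows(problem, x),
    )


def _extreme_nutrient(categories: pd.DataFrame, cs: ConstraintSet,
                      nutrient: str, maximize: bool) -> LPSolution:
    problem = to_lp_problem(categories, cs)
    per_g = categories.set_index("category_id")[nutrient].to_numpy(float) / 100.0
    c = -per_g if maximize else per_g
    res = _solve(problem, c)
    sol = _solution_from(categories, problem, res)
    if sol.status == OPTIMAL:
        sol.objective_value = float(sol.totals[nutrient])
    return sol


def solve_max_potassium(categories: pd.DataFrame,
                        cs: ConstraintSet) -> LPSolution:
    """Maximize total daily potassium subject to the constraint set.

    An unbounded status signals a modeling error (no energy equality or
    finite upper bounds to cap the diet).
    """
    if len(categories) == 0:
        raise ValueError("no categories")
    return _extreme_nutrient(categories, cs, POTASSIUM, maximize=True)


def solve_min_potassium(categories: pd.DataFrame,
                        cs: ConstraintSet) -> LPSolution:
    """Minimize total daily potassium (lower envelope of the region)."""
    if len(categories) == 0:
        raise ValueError("no categories")
    return _extreme_nutrient(categories, cs, POTASSIUM, maximize=False)


def solve_extreme_sodium(categories: pd.DataFrame, cs: ConstraintSet,
                         maximize: bool) -> LPSolution:
    """Extremize total daily sodium (used to bracket feasible Na levels)."""
    return _extreme_nutrient(categories, cs, SODIUM, maximize=maximize)


def deviation_weights(observed: ObservedPattern,
                      weighting: str = "inverse_mean") -> pd.Series:
    """Per-category weights of the deviation functional.

    ``inverse_mean`` (default): 1 / observed mean amount, so deviations are
    relative to habitual portion size; categories with zero observed mean
    get 1 / (mean positive portion) to keep the functional finite.
    ``uniform``: plain L1 in grams.
    """
    obs = observed.amounts.astype(float)
    if weighting == "uniform":
        return pd.Series(1.0, index=obs.index)
    if weighting != "inverse_mean":
        raise ValueError(f"unknown weighting {weighting!r}")
    positive = obs[obs > 0]
    fallback = 1.0 / positive.mean() if len(positive) else 1.0
    w = pd.Series(fallback, index=obs.index)
    w[obs > 0] = 1.0 / obs[obs > 0]
    return w


def solve_min_deviation(
    categories: pd.DataFrame,
    cs: ConstraintSet,
    observed: ObservedPattern,
    weighting: str = "inverse_mean",
) -> LPSolution:
    """Find the feasible pattern closest to the observed diet.

    The deviation functional sum_i w_i |x_i - obs_i| is linearized with
    split variables: x_i - obs_i = d+_i - d-_i with d± >= 0 and objective
    sum_i w_i (d+_i + d-_i).  ``deviation_score`` is its optimal value.
    """
    if len(categories) == 0:
        raise ValueError("no categories")
    problem = to_lp_problem(categories, cs)
    n = len(problem.variables)
    obs = observed.amounts.reindex(problem.variables)
    if obs.isna().any():
        missing = list(obs.index[obs.isna()])[:5]
        raise ValueError(f"observed pattern missing categories: {missing}")
    w = deviation_weights(observed, weighting).reindex(problem.variables)

    # augmented system over [x, d+, d-]
    Z = np.zeros((len(problem.b_ub), n)) if problem.b_ub.size else \
        np.empty((0, n))
    A_ub = np.hstack([problem.A_ub, Z, Z]) if problem.b_ub.size else None
    eye = np.eye(n)
    A_eq = np.vstack([
        np.hstack([problem.A_eq, np.zeros((len(problem.b_eq), 2 * n))]),
        np.hstack([eye, -eye, eye]),
    ])
    b_eq = np.concatenate([problem.b_eq, obs.to_numpy(float)])
    c = np.concatenate([np.zeros(n), w.to_numpy(float), w.to_numpy(float)])

    res = linprog(c, A_ub=A_ub,
                  b_ub=problem.b_ub if problem.b_ub.size else None,
                  A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    status = _statuses(res)
    if status != OPTIMAL:
        return LPSolution(status=status, amounts=None, objective_value=None,
                          totals=None)
    x = np.maximum(res.x[:n], 0.0)
    _check_feasible(problem, x)
    # recompute the score from x itself (split variables can both be
    # positive off-optimum only; at optimum this equals res.fun)
    score = float(w.to_numpy() @ np.abs(x - obs.to_numpy(float)))
    amounts = pd.Series(x, index=problem.variables, name="g_per_day")
    return LPSolution(
        status=OPTIMAL, amounts=amounts, objective_value=score,
        totals=pattern_totals(categories, amounts), deviation_score=score,
        binding=_binding_rows(problem, x),
    )


# --------------------------------------------------------------------------
# brute-force oracle
# --------------------------------------------------------------------------

def brute_force_optimum(
    categories: pd.DataFrame,
    cs: ConstraintSet,
    objective: str,
    grid_step: float = 1.0,
    observed: ObservedPattern | None = None,
    weighting: str = "inverse_mean",
    max_axis_points: int = 1500,
):
    """Grid-scan oracle for instances with at most three categories.

    One variable is eliminated through the energy equality; the remaining
    free variables (at most two) are scanned over their energy-implied
    boxes.  With one free variable the scan is exhaustive at ``grid_step``
    grams.  With two, an exhaustive coarse scan (at most
    ``max_axis_points`` per axis) is refined repeatedly around the
    incumbent until the cell size reaches ``grid_step``; feasibility is
    checked with a tolerance proportional to the current cell size, so the
    result converges to the LP optimum as ``grid_step -> 0``.

    Returns ``(status, best_value, best_x)`` with ``best_x`` a Series of
    g/d; ``objective`` is ``"max_potassium"`` or ``"min_deviation"``
    (requires ``observed``).
    """
    if len(categories) > 3:
        raise ValueError("brute-force oracle limited to <= 3 categories")
    if objective not in ("max_potassium", "min_deviation"):
        raise ValueError(f"unknown objective {objective!r}")
    if objective == "min_deviation" and observed is None:
        raise ValueError("min_deviation requires an observed pattern")

    problem = to_lp_problem(categories, cs)
    n = len(problem.variables)
    e = problem.A_eq[0]          # per-gram energy row (kcal/g)
    E = problem.b_eq[0]
    if (e <= 0).any():
        raise ValueError("oracle requires positive energy density")
    # eliminate the last variable via the energy equality
    free = list(range(n - 1))
    ubox = E / e                 # per-variable cap from energy alone

    kcol = categories.set_index("category_id")[POTASSIUM].to_numpy(float) / 100.0
    if objective == "min_deviation":
        obs = observed.amounts.reindex(problem.variables).to_numpy(float)
        w = deviation_weights(observed, weighting).reindex(
            problem.variables).to_numpy(float)

    other_eq = problem.A_eq[1:], problem.b_eq[1:]

    def evaluate(grid_cols, step):
        """grid_cols: list of 1-D arrays per free variable (broadcastable)."""
        if free:
            mesh = np.meshgrid(*grid_cols, indexing="ij")
            X = np.stack([m.ravel() for m in mesh], axis=1)
        else:
            X = np.zeros((1, 0))
        xlast = (E - X @ e[free]) / e[-1]
        ok = xlast >= -step
        pts = np.column_stack([X, np.maximum(xlast, 0.0)])
        # tolerance: moving each coordinate by one step changes a row by at
        # most step * sum|a|
        A_eq2, b_eq2 = other_eq
        for a, b in zip(A_eq2, b_eq2):
            tol = step * np.abs(a).sum() + FEAS_RTOL * max(abs(b), 1.0)
            ok &= np.abs(pts @ a - b) <= tol
        if problem.b_ub.size:
            for a, b in zip(problem.A_ub, problem.b_ub):
                tol = step * np.abs(a).sum() + FEAS_RTOL * max(abs(b), 1.0)
                ok &= pts @ a <= b + tol
        if not ok.any():
            return None, None
        pts = pts[ok]
        if objective == "max_potassium":
            vals = pts @ kcol
            i = int(np.argmax(vals))
        else:
            vals = np.abs(pts - obs) @ w
            i = int(np.argmin(vals))
        return float(vals[i]), pts[i]

    lo = np.zeros(len(free))
    hi = np.array([ubox[i] for i in free])
    step = grid_step
    if len(free) == 2:
        span = (hi - lo).max()
        step = max(grid_step, span / max_axis_points)

    best = None
    while True:
        cols = [np.arange(lo[i], hi[i] + step / 2, step)
                if hi[i] > lo[i] else np.array([lo[i]])
                for i in range(len(free))]
        val, x = evaluate(cols, step)
        if x is not None:
            best = (val, x)
        if step <= grid_step * (1 + 1e-9):
            break
        if x is None:
            # nothing feasible at this resolution: refine globally
            step = max(grid_step, step / 4)
            continue
        # refine around the incumbent
        center = x[: len(free)]
        width = 3 * step
        lo = np.maximum(center - width, 0.0)
        hi = np.minimum(center + width, np.array([ubox[i] for i in free]))
        step = max(grid_step, step / 4)

    if best is None:
        return INFEASIBLE, None, None
    val, x = best
    return OPTIMAL, val, pd.Series(x, index=problem.variables)
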