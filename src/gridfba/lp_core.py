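"""Linear-programming backend for cell-scale and regional models.

Solves maximise ``c.v`` subject to ``S v = 0`` and ``l <= v <= u`` with
scipy's HiGHS solver, which is deterministic for a fixed model and variable
ordering.  Only the optimal objective value is unique in general — the flux
vector may be one of several degenerate optima — so downstream analyses
aggregate fluxes in ways that are invariant across alternate optima, or pin
the split by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .cell_model import CellScaleModel
from .discretiser import RegionalModel

__all__ = ["LPSolution", "solve", "solve_cell_scale", "verify_steady_state"]

FEASIBILITY_TOL = 1e-9
STEADY_STATE_TOL = 1e-6


@dataclass
class LPSolution:
    status: str                      # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float]
    residual: float | None           # max |(S v)_m| over metabolite rows

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux_sum(self, names) -> float:
        return float(sum(self.fluxes[n] for n in names))


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve_arrays(c, S, lower, upper, names) -> LPSolution:
    bounds = [
        (None if lo == -np.inf else lo, None if hi == np.inf else hi)
        for lo, hi in zip(lower, upper)
    ]
    res = linprog(
        -np.asarray(c, dtype=float),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return LPSolution(status, None, {}, None)
    v = res.x
    residual = float(np.max(np.abs(S @ v))) if S.shape[0] else 0.0
    return LPSolution(
        "optimal",
        float(-res.fun),
        dict(zip(names, map(float, v))),
        residual,
    )


def solve(model: RegionalModel, parsimonious: bool = False) -> LPSolution:
    """Solve a discretised regional model.

    With ``parsimonious=True`` a second LP fixes the optimal objective and
    minimises the total absolute flux, selecting the sparsest-flow optimum;
    the default reports the plain optimum since objective-level results do
    not depend on it.
    """
    if model.n_variables == 0:
        raise ValueError("model has no variables")
    sol = _solve_arrays(
        model.objective, model.S, model.lower, model.upper, model.variables
    )
    if not parsimonious or not sol.optimal:
        return sol
    return _parsimonious(model, sol.objective_value)


def _parsimonious(model: RegionalModel, z_opt: float) -> LPSolution:
    # minimise sum t with t >= v, t >= -v, c.v = z_opt
    n = model.n_variables
    S = model.S
    m = S.shape[0]
    A_eq = sparse.hstack([S, sparse.csr_matrix((m, n))])
    A_eq = sparse.vstack(
        [A_eq, sparse.hstack([sparse.csr_matrix(model.objective), sparse.csr_matrix((1, n))])]
    ).tocsr()
    b_eq = np.zeros(m + 1)
    b_eq[-1] = z_opt
    eye = sparse.eye(n)
    A_ub = sparse.vstack(
        [sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])]
    ).tocsr()
    b_ub = np.zeros(2 * n)
    c = np.concatenate([np.zeros(n), np.ones(n)])
    bounds = [
        (None if lo == -np.inf else lo, None if hi == np.inf else hi)
        for lo, hi in zip(model.lower, model.upper)
    ] + [(0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        # fall back to the plain optimum rather than failing
        return _solve_arrays(model.objective, model.S, model.lower, model.upper, model.variables)
    v = res.x[:n]
    residual = float(np.max(np.abs(model.S @ v)))
    return LPSolution("optimal", z_opt, dict(zip(model.variables, map(float, v))), residual)


def solve_cell_scale(model: CellScaleModel) -> LPSolution:
    """Conventional (non-spatial) FBA on a cell-scale model.

    Applies the ``kcat * [E]`` capacity cap of each catalysed reaction at
    the whole-cell level and maximises the model's objective.
    """
    S = sparse.csr_matrix(model.stoichiometric_matrix())
    bounds = [model.capacity_bounds(r) for r in model.reactions]
    lower = np.array([b[0] for b in bounds])
    upper = np.array([b[1] for b in bounds])
    return _solve_arrays(model.objective_vector(), S, lower, upper, model.reaction_ids)


def verify_steady_state(
    solution: LPSolution, model: RegionalModel, tol: float = STEADY_STATE_TOL
) -> tuple[bool, str, float]:
    """Check ``S v = 0`` row by row; returns (ok, worst row name, worst residual)."""
    if not solution.optimal and solution.fluxes == {}:
        raise ValueError("steady-state check requires a solved flux vector")
    v = np.array([solution.fluxes[name] for name in model.variables])
    resid = np.abs(model.S @ v)
    worst = int(np.argmax(resid)) if resid.size else 0
    worst_val = float(resid[worst]) if resid.size else 0.0
    return worst_val <= tol, model.metabolite_rows[worst], worst_val
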