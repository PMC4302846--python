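"""Linear-programming analyses of an assembled model.

All problems are of the form  min/max c.v  s.t.  S.v = b, lb <= v <= ub and
are solved with the HiGHS dual simplex through :func:`scipy.optimize.linprog`.
Feasibility/optimality tolerances of 1e-9 are requested from the backend;
tests assert agreement at 1e-6, which is what genome-scale LPs in double
precision reliably deliver.

* :func:`fba_min_photon` — the photon-minimization flux balance problem.
* :func:`fba_l1_representative` — among the photon-optimal solutions, the one
  of minimal total flux (L1 norm), via the standard v = v+ - v- splitting.
* :func:`fva` — per-flux min/max with the photon objective fixed at (a
  fraction gamma of) its optimum, and blocked-reaction detection.
* :func:`remove_blocked` — drop blocked columns; the feasible polytope is
  unchanged (every feasible point of the reduced model extends by zeros).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import ModelError, WholePlantModel

__all__ = [
    "FluxSolution",
    "FVAResult",
    "LPProblem",
    "solve_lp",
    "fba_min_photon",
    "fba_l1_representative",
    "fva",
    "remove_blocked",
    "BLOCKED_TOL",
]

#: a flux whose FVA bounds both fall below this magnitude is blocked
BLOCKED_TOL = 1e-9

_SOLVER_OPTIONS = {
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded",
           4: "numerical"}


class OptimizationError(RuntimeError):
    pass


@dataclass
class LPResult:
    status: str
    objective: float | None
    x: np.ndarray | None
    eq_duals: np.ndarray | None = None
    lower_duals: np.ndarray | None = None
    upper_duals: np.ndarray | None = None


@dataclass
class LPProblem:
    """min c.x  s.t.  A.x = b, lb <= x <= ub  (maximize via sense=-1)."""

    c: np.ndarray
    A: sparse.spmatrix
    b: np.ndarray
    lb: np.ndarray
    ub: np.ndarray

    def solve(self, sense: int = 1) -> LPResult:
        have_eq = self.A.shape[0] > 0
        res = linprog(
            sense * self.c,
            A_eq=self.A if have_eq else None,
            b_eq=self.b if have_eq else None,
            bounds=np.column_stack([self.lb, self.ub]),
            method="highs-ds",
            options=dict(_SOLVER_OPTIONS),
        )
        status = _STATUS.get(res.status, "numerical")
        if status != "optimal":
            return LPResult(status, None, None)
        eq_duals = (
            sense * np.asarray(res.eqlin.marginals) if have_eq else np.zeros(0)
        )
        return LPResult(
            "optimal",
            sense * res.fun,
            res.x,
            eq_duals=eq_duals,
            lower_duals=sense * np.asarray(res.lower.marginals),
            upper_duals=sense * np.asarray(res.upper.marginals),
        )

    def duality_gap(self, result: LPResult) -> float:
        """|primal - dual| objective gap; zero at a true optimum.

        The dual objective is b.y + lb.mu_lb + ub.mu_ub in scipy's marginal
        sign convention; infinite bounds carry zero multipliers.
        """
        if result.status != "optimal":
            raise OptimizationError("duality gap undefined off the optimum")
        dual = float(self.b @ result.eq_duals)
        lb_term = np.where(np.isfinite(self.lb), self.lb, 0.0) @ result.lower_duals
        ub_term = np.where(np.isfinite(self.ub), self.ub, 0.0) @ result.upper_duals
        dual += float(lb_term + ub_term)
        return abs(float(self.c @ result.x) - dual)


def model_lp(model: WholePlantModel) -> LPProblem:
    lb, ub = model.bounds()
    return LPProblem(
        c=model.objective_vector(),
        A=model.matrix().tocsc(),
        b=np.zeros(model.n_rows),
        lb=lb,
        ub=ub,
    )


def solve_lp(problem: LPProblem, sense: int = 1) -> LPResult:
    return problem.solve(sense=sense)


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


@dataclass
class FluxSolution:
    objective_value: float | None
    fluxes: dict[str, float]
    status: str
    l1_norm: float | None = None

    def __getitem__(self, flux_id: str) -> float:
        return self.fluxes[flux_id]


def fba_min_photon(model: WholePlantModel) -> FluxSolution:
    """Minimize the time-fraction-weighted photon uptake at steady state."""
    if not np.any(model.objective_vector()):
        raise ModelError("model has an all-zero objective vector")
    problem = model_lp(model)
    res = problem.solve()
    if res.status != "optimal":
        return FluxSolution(None, {}, res.status)
    fluxes = dict(zip(model.column_ids, res.x))
    return FluxSolution(res.objective, fluxes, "optimal")


def _with_objective_fixed(
    problem: LPProblem, f: np.ndarray, z_opt: float
) -> LPProblem:
    A = sparse.vstack([problem.A, sparse.csr_matrix(f)])
    b = np.append(problem.b, z_opt)
    return LPProblem(problem.c.copy(), A.tocsc(), b, problem.lb, problem.ub)


def fba_l1_representative(
    model: WholePlantModel, z_opt: float | None = None
) -> FluxSolution:
    """Minimal-L1-norm flux vector among the photon-optimal solutions.

    Each flux is split as v = v+ - v- with v+/- >= 0 and sum(v+ + v-) is
    minimized subject to the mass balances and f.v = z_opt; the returned
    fluxes are the net values.  If ``z_opt`` is omitted it is computed first.
    """
    if z_opt is None:
        sol = fba_min_photon(model)
        if sol.status != "optimal":
            return sol
        z_opt = sol.objective_value
    base = model_lp(model)
    n = len(base.c)
    f = base.c
    # v+ in [max(lb,0), max(ub,0)], v- in [max(-ub,0), max(-lb,0)] keeps
    # v = v+ - v- exactly within [lb, ub]
    lb_p, ub_p = np.maximum(base.lb, 0.0), np.maximum(base.ub, 0.0)
    lb_m, ub_m = np.maximum(-base.ub, 0.0), np.maximum(-base.lb, 0.0)
    A_split = sparse.hstack([base.A, -base.A])
    A_obj = sparse.hstack(
        [sparse.csr_matrix(f), -sparse.csr_matrix(f)]
    )
    problem = LPProblem(
        c=np.ones(2 * n),
        A=sparse.vstack([A_split, A_obj]).tocsc(),
        b=np.append(base.b, z_opt),
        lb=np.concatenate([lb_p, lb_m]),
        ub=np.concatenate([ub_p, ub_m]),
    )
    res = problem.solve()
    if res.status == "infeasible":
        raise OptimizationError(
            f"photon objective = {z_opt!r} is infeasible as an equality; "
            "re-derive z_opt with fba_min_photon or relax the tolerance"
        )
    if res.status != "optimal":
        return FluxSolution(None, {}, res.status)
    v = res.x[:n] - res.x[n:]
    return FluxSolution(
        z_opt, dict(zip(model.column_ids, v)), "optimal",
        l1_norm=float(res.objective),
    )


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------


@dataclass
class FVAResult:
    minimum: dict[str, float]
    maximum: dict[str, float]
    optimum_fixed_at: float
    blocked: set[str] = field(default_factory=set)

    def range(self, flux_id: str) -> tuple[float, float]:
        return self.minimum[flux_id], self.maximum[flux_id]

    def classify(self, fixed_tol: float = 1e-6) -> dict[str, str]:
        """Label each flux blocked / fixed (nonzero, zero range) / variable."""
        out = {}
        for fid in self.minimum:
            lo, hi = self.minimum[fid], self.maximum[fid]
            if fid in self.blocked:
                out[fid] = "blocked"
            elif hi - lo < fixed_tol:
                out[fid] = "fixed"
            else:
                out[fid] = "variable"
        return out


def fva(
    model: WholePlantModel,
    z_opt: float | None = None,
    gamma: float = 1.0,
) -> FVAResult:
    """Per-flux min/max with the photon objective fixed at gamma * z_opt.

    The optimum is imposed as an equality (the gamma knob covers the common
    relaxed variant; gamma defaults to 1).  A flux with both extrema below
    ``BLOCKED_TOL`` in magnitude is blocked.
    """
    if not 0.0 < gamma <= 1.0:
        raise ModelError(f"gamma must lie in (0, 1], got {gamma}")
    if z_opt is None:
        sol = fba_min_photon(model)
        if sol.status != "optimal":
            raise OptimizationError(f"photon FBA is {sol.status}")
        z_opt = sol.objective_value
    base = model_lp(model)
    fixed = _with_objective_fixed(base, base.c, gamma * z_opt)
    n = len(base.c)
    minimum: dict[str, float] = {}
    maximum: dict[str, float] = {}
    blocked: set[str] = set()
    col_ids = model.column_ids
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        sub = LPProblem(c, fixed.A, fixed.b, fixed.lb, fixed.ub)
        lo = sub.solve(sense=1)
        hi = sub.solve(sense=-1)
        if lo.status != "optimal" or hi.status != "optimal":
            bad = lo.status if lo.status != "optimal" else hi.status
            raise OptimizationError(f"FVA sub-LP for {col_ids[j]!r} is {bad}")
        minimum[col_ids[j]] = lo.objective
        maximum[col_ids[j]] = hi.objective
        if abs(lo.objective) < BLOCKED_TOL and abs(hi.objective) < BLOCKED_TOL:
            blocked.add(col_ids[j])
    return FVAResult(minimum, maximum, gamma * z_opt, blocked)


def remove_blocked(model: WholePlantModel, fva_result: FVAResult) -> WholePlantModel:
    """Return a copy of the model without the blocked columns.

    Since blocked fluxes are zero in every feasible point (at the fixed
    optimum), dropping them leaves the polytope unchanged up to extension by
    zeros.  Idempotent.
    """
    reduced = WholePlantModel(model.base)
    for rid in model.row_ids:
        reduced.add_row(rid, model.row_info[rid])
    for col in model.columns:
        if col.id in fva_result.blocked:
            continue
        reduced.add_column(col.id, dict(col.stoich), col.lb, col.ub,
                           col.info, col.objective)
    return reduced
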