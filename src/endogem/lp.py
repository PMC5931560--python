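"""Thin linear-programming layer over scipy's HiGHS interface.

All steady-state LPs in the package go through :class:`SteadyStateLp`, which
holds the dense stoichiometric matrix and box bounds of one model and solves

    optimise  c . v   subject to  S v = 0,  lb <= v <= ub  (+ optional rows)

The solver is HiGHS via ``scipy.optimize.linprog``; feasibility tolerances are
tightened to 1e-10 so optimal solutions satisfy |S v| below 1e-9 on the model
sizes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

FEASIBILITY_TOL = 1e-9

_HIGHS_OPTIONS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-9,
    "presolve": True,
}

__all__ = ["LpResult", "SteadyStateLp", "FEASIBILITY_TOL"]


@dataclass
class LpResult:
    status: str  # optimal | infeasible | unbounded
    objective: float | None
    x: np.ndarray | None


class SteadyStateLp:
    """LP problem S v = 0 with box bounds for one model."""

    def __init__(self, model):
        S, mids, rids = model.stoichiometric_matrix()
        self.S = S
        self.metabolite_ids = mids
        self.reaction_ids = rids
        self.index = {r: i for i, r in enumerate(rids)}
        self.lb, self.ub = model.bounds_arrays()

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    def objective_vector(self, coefficients: dict[str, float]) -> np.ndarray:
        c = np.zeros(self.n)
        for rid, coef in coefficients.items():
            c[self.index[rid]] = coef
        return c

    def solve(
        self,
        c: np.ndarray,
        maximize: bool = True,
        lb: np.ndarray | None = None,
        ub: np.ndarray | None = None,
        A_ub: np.ndarray | None = None,
        b_ub: np.ndarray | None = None,
        extra_cols: int = 0,
        extra_bounds: list[tuple[float | None, float | None]] | None = None,
    ) -> LpResult:
        """Solve the LP; `extra_cols` appends auxiliary variables with zero
        stoichiometry (used by FASTCORE's LP7/LP10 and elastic relaxation)."""
        lb = self.lb if lb is None else lb
        ub = self.ub if ub is None else ub
        n_total = self.n + extra_cols
        A_eq = self.S
        if extra_cols:
            A_eq = np.hstack([self.S, np.zeros((self.S.shape[0], extra_cols))])
        bounds = [
            (None if not np.isfinite(lo) else lo, None if not np.isfinite(hi) else hi)
            for lo, hi in zip(lb, ub)
        ]
        if extra_cols:
            bounds += list(extra_bounds or [(None, None)] * extra_cols)
        cc = np.asarray(c, dtype=float)
        if cc.size != n_total:
            raise ValueError("objective length mismatch")
        res = linprog(
            -cc if maximize else cc,
            A_eq=A_eq,
            b_eq=np.zeros(A_eq.shape[0]),
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=bounds,
            method="highs",
            options=dict(_HIGHS_OPTIONS),
        )
        if res.status == 0:
            obj = float(-res.fun if maximize else res.fun)
            return LpResult("optimal", obj, np.asarray(res.x))
        if res.status == 2:
            return LpResult("infeasible", None, None)
        if res.status == 3:
            return LpResult("unbounded", None, None)
        return LpResult("infeasible", None, None)

    def feasible_point(self) -> LpResult:
        return self.solve(np.zeros(self.n), maximize=False)
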