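"""Linear-programming analyses of metabolic models.

Flux balance analysis (FBA), flux variability analysis (FVA), flux-consistency
testing, single gene/reaction essentiality, minimal-cardinality relaxation of
exchange bounds, and carbon-source preference queries.  All solves go through
:class:`endogem.lp.SteadyStateLp` (HiGHS).

Conventions: the FBA objective is the model's biomass reaction; essentiality
compares the knockout optimum to the wild-type optimum (a gene knockout closes
every reaction whose GPR evaluates false once the gene is called absent);
exchange fluxes are positive for secretion, negative for uptake.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .lp import FEASIBILITY_TOL, SteadyStateLp
from .model_io import ABSENT, PRESENT, MetabolicModel, Reaction

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-4  # flux-consistency threshold
DEFAULT_ESSENTIALITY_THRESHOLD = 0.01  # growth ratio below which an entity is essential

__all__ = [
    "FluxSolution",
    "FvaResult",
    "EssentialityResult",
    "InfeasibleModelError",
    "fba",
    "fva",
    "consistent_reactions",
    "essential_entities",
    "relax_to_feasibility",
    "max_product_from_source",
    "DEFAULT_EPSILON",
    "DEFAULT_ESSENTIALITY_THRESHOLD",
]


class InfeasibleModelError(RuntimeError):
    """Raised when an analysis requires a feasible (or growing) model."""


@dataclass
class FluxSolution:
    objective_value: float | None
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class FvaResult:
    ranges: dict[str, tuple[float, float]]
    fraction_of_optimum: float = 0.0

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]

    def items(self):
        return self.ranges.items()


@dataclass
class EssentialityResult:
    kind: str  # gene | reaction
    growth_ratio: dict[str, float]
    threshold: float = DEFAULT_ESSENTIALITY_THRESHOLD
    wild_type_objective: float = 0.0

    @property
    def essential(self) -> set[str]:
        return {e for e, r in self.growth_ratio.items() if r < self.threshold}


def fba(model: MetabolicModel, objective_id: str | None = None) -> FluxSolution:
    """Maximise the objective (biomass) flux subject to S v = 0 and bounds."""
    rid = objective_id or model.objective_reaction_id
    if not rid:
        raise ValueError("model has no objective reaction")
    prob = SteadyStateLp(model)
    res = prob.solve(prob.objective_vector({rid: 1.0}))
    if res.status != "optimal":
        return FluxSolution(None, {}, res.status)
    return FluxSolution(
        res.objective, dict(zip(prob.reaction_ids, res.x)), "optimal"
    )


def fva(
    model: MetabolicModel,
    fraction_of_optimum: float = 0.0,
    reactions: list[str] | None = None,
) -> FvaResult:
    """Per-reaction minimum/maximum flux, optionally at near-optimal growth.

    ``fraction_of_optimum=0`` (the default) explores the full steady-state
    polytope; patient-model bounds in this package are derived from sampling
    of that space, not from growth-constrained variability.
    """
    prob = SteadyStateLp(model)
    A_ub = b_ub = None
    if fraction_of_optimum > 0:
        sol = fba(model)
        if sol.status != "optimal":
            raise InfeasibleModelError(f"FVA requires a feasible model (FBA status {sol.status})")
        c_obj = prob.objective_vector({model.objective_reaction_id: 1.0})
        A_ub = -c_obj[None, :]
        b_ub = np.array([-fraction_of_optimum * sol.objective_value])
    ranges: dict[str, tuple[float, float]] = {}
    for rid in reactions or prob.reaction_ids:
        c = prob.objective_vector({rid: 1.0})
        lo = prob.solve(c, maximize=False, A_ub=A_ub, b_ub=b_ub)
        hi = prob.solve(c, maximize=True, A_ub=A_ub, b_ub=b_ub)
        if lo.status != "optimal" or hi.status != "optimal":
            raise InfeasibleModelError(f"FVA subproblem for {rid} was {lo.status}/{hi.status}")
        ranges[rid] = (lo.objective, hi.objective)
    return FvaResult(ranges, fraction_of_optimum)


def consistent_reactions(model: MetabolicModel, epsilon: float = DEFAULT_EPSILON) -> set[str]:
    """Reactions that can carry |v| >= epsilon in some feasible steady state.

    Reversible reactions are tested in both directions; the complement of the
    returned set is the blocked set.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    prob = SteadyStateLp(model)
    tol = epsilon * 1e-3
    consistent: set[str] = set()
    for rid in prob.reaction_ids:
        c = prob.objective_vector({rid: 1.0})
        hi = prob.solve(c, maximize=True)
        if hi.status == "unbounded" or (hi.status == "optimal" and hi.objective >= epsilon - tol):
            consistent.add(rid)
            continue
        if model.reaction(rid).lower_bound < 0:
            lo = prob.solve(c, maximize=False)
            if lo.status == "unbounded" or (
                lo.status == "optimal" and lo.objective <= -epsilon + tol
            ):
                consistent.add(rid)
    return consistent


def _gene_knockout_closed_reactions(model: MetabolicModel, gene: str) -> list[str]:
    """Reactions disabled when `gene` is absent and all other genes present."""
    closed = []
    for r in model.reactions:
        if gene in r.gpr.genes():
            calls = {g: PRESENT for g in r.gpr.genes()}
            calls[gene] = ABSENT
            if not r.gpr.evaluate(calls):
                closed.append(r.id)
    return closed


def essential_entities(
    model: MetabolicModel,
    kind: str = "gene",
    threshold: float = DEFAULT_ESSENTIALITY_THRESHOLD,
) -> EssentialityResult:
    """Single-knockout essentiality scan for genes or reactions.

    A gene knockout sets the gene absent and closes reactions whose GPR becomes
    false; a reaction knockout forces its bounds to zero.  The growth ratio is
    the knockout FBA optimum over the wild-type optimum.
    """
    if kind not in ("gene", "reaction"):
        raise ValueError(f"kind must be 'gene' or 'reaction', got {kind!r}")
    wt = fba(model)
    if wt.status != "optimal" or wt.objective_value is None or wt.objective_value <= FEASIBILITY_TOL:
        raise InfeasibleModelError("essentiality undefined: wild-type optimum is not positive")
    prob = SteadyStateLp(model)
    c_obj = prob.objective_vector({model.objective_reaction_id: 1.0})
    ratios: dict[str, float] = {}
    entities = sorted(model.genes) if kind == "gene" else prob.reaction_ids
    for entity in entities:
        closed = (
            _gene_knockout_closed_reactions(model, entity)
            if kind == "gene"
            else [entity]
        )
        lb = prob.lb.copy()
        ub = prob.ub.copy()
        for rid in closed:
            j = prob.index[rid]
            lb[j] = 0.0
            ub[j] = 0.0
        res = prob.solve(c_obj, maximize=True, lb=lb, ub=ub)
        ko_obj = res.objective if res.status == "optimal" else 0.0
        ratios[entity] = max(0.0, min(1.0, ko_obj / wt.objective_value))
    return EssentialityResult(kind, ratios, threshold, wt.objective_value)


def relax_to_feasibility(
    model: MetabolicModel,
    candidate_exchange_ids: list[str],
    wide_bounds: tuple[float, float] = (-1000.0, 1000.0),
    max_exact_candidates: int = 12,
) -> tuple[MetabolicModel, set[str]]:
    """Open a minimal number of candidate exchange bounds to restore feasibility.

    For up to ``max_exact_candidates`` candidates the minimal-cardinality set is
    found exactly by incremental-size subset enumeration; above that an elastic
    LP (minimise summed bound violations, then count nonzero slacks) is used.
    Relaxed exchanges are reset to ``wide_bounds``.
    """
    for rid in candidate_exchange_ids:
        if not model.reaction(rid).is_exchange:
            raise ValueError(f"candidate {rid!r} is not an exchange reaction")
    prob = SteadyStateLp(model)
    if prob.feasible_point().status == "optimal":
        return model, set()

    def _with_relaxed(subset: tuple[str, ...]) -> MetabolicModel:
        relaxed = model.copy()
        for rid in subset:
            rxn = relaxed.reaction(rid)
            rxn.lower_bound, rxn.upper_bound = wide_bounds
        return relaxed

    candidates = sorted(candidate_exchange_ids)
    if len(candidates) <= max_exact_candidates:
        for size in range(1, len(candidates) + 1):
            for subset in itertools.combinations(candidates, size):
                relaxed = _with_relaxed(subset)
                if SteadyStateLp(relaxed).feasible_point().status == "optimal":
                    return relaxed, set(subset)
        raise InfeasibleModelError(
            "model remains infeasible after relaxing all candidate exchanges"
        )

    # Elastic heuristic: v_i may exceed its box by slacks s_lo, s_hi >= 0 on
    # candidates only; minimise total slack, then relax the violated exchanges.
    n = prob.n
    k = len(candidates)
    idx = [prob.index[rid] for rid in candidates]
    lb = prob.lb.copy()
    ub = prob.ub.copy()
    big = max(abs(wide_bounds[0]), abs(wide_bounds[1]))
    for j in idx:
        lb[j] = -big
        ub[j] = big
    # A_ub rows: v_j - s_hi_j <= ub_j ; -v_j - s_lo_j <= -lb_j
    A_ub = np.zeros((2 * k, n + 2 * k))
    b_ub = np.zeros(2 * k)
    for row, j in enumerate(idx):
        A_ub[row, j] = 1.0
        A_ub[row, n + row] = -1.0
        b_ub[row] = prob.ub[j]
        A_ub[k + row, j] = -1.0
        A_ub[k + row, n + k + row] = -1.0
        b_ub[k + row] = -prob.lb[j]
    c = np.concatenate([np.zeros(n), np.ones(2 * k)])
    res = prob.solve(
        c,
        maximize=False,
        lb=lb,
        ub=ub,
        A_ub=A_ub,
        b_ub=b_ub,
        extra_cols=2 * k,
        extra_bounds=[(0.0, 2 * big)] * (2 * k),
    )
    if res.status != "optimal":
        raise InfeasibleModelError(
            "model remains infeasible after relaxing all candidate exchanges"
        )
    slacks = res.x[n:]
    relaxed_set = {
        candidates[i]
        for i in range(k)
        if slacks[i] > 1e-9 or slacks[k + i] > 1e-9
    }
    relaxed = _with_relaxed(tuple(sorted(relaxed_set)))
    if SteadyStateLp(relaxed).feasible_point().status != "optimal":
        raise InfeasibleModelError("elastic relaxation failed to restore feasibility")
    return relaxed, relaxed_set


def max_product_from_source(
    model: MetabolicModel,
    product_metabolite: str,
    source_exchange: str,
    demand_upper: float = 1e6,
) -> float:
    """Maximal production flux of a metabolite with a single open carbon source.

    All exchange reactions of carbon-containing metabolites other than
    ``source_exchange`` are closed for uptake; a temporary demand sink for the
    product is added and maximised.  Used pairwise to ask, e.g., whether a model
    can make more acetyl-CoA from palmitate than from glucose.
    """
    if product_metabolite not in {m.id for m in model.metabolites}:
        raise KeyError(f"product metabolite {product_metabolite!r} not in model")
    if not model.reaction(source_exchange).is_exchange:
        raise ValueError(f"{source_exchange!r} is not an exchange reaction")
    work = model.copy()
    for rxn in work.exchange_reactions:
        if rxn.id == source_exchange:
            continue
        met = work.metabolite(rxn.exchanged_metabolite())
        if met.n_carbons > 0 and rxn.lower_bound < 0:
            rxn.lower_bound = 0.0
    demand_id = f"DM_{product_metabolite}"
    while work.has_reaction(demand_id):
        demand_id += "_"
    work.reactions.append(
        Reaction(demand_id, {product_metabolite: -1.0}, 0.0, demand_upper)
    )
    work._reindex()
    sol = fba(work, objective_id=demand_id)
    if sol.status != "optimal":
        raise InfeasibleModelError(f"product maximisation was {sol.status}")
    return sol.objective_value
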