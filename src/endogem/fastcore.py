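"""Context-specific model extraction with the FASTCORE two-phase LP scheme.

Given a flux-consistent genome-scale model and a *core* set of reactions that
must remain active, extraction returns a compact flux-consistent submodel
containing the core.  The core is built from transcript present/absent calls:
every reaction whose GPR is satisfied by the non-absent transcripts (plus the
biomass objective, which is always force-included) must carry flux of at least
``epsilon`` in the extracted network.

The algorithm alternates two LPs:

* LP7 maximises the number of core reactions carrying flux >= epsilon
  (auxiliary variables z_i <= v_i, z_i in [0, epsilon]).
* LP10 finds a minimal-support flux (L1 on the non-core penalty set) that keeps
  the currently reachable core members at >= epsilon.

Reversible core reactions that cannot be activated forwards are retried with
flipped bounds; a singleton fallback handles stragglers.  Tie-breaking is
deterministic: reactions are processed in lexicographic id order.  The result
is verified (and minimally cleaned) so every kept reaction is flux-consistent
within the extracted submodel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .lp import SteadyStateLp
from .lp_analysis import DEFAULT_EPSILON, consistent_reactions
from .model_io import ExpressionProfile, MetabolicModel, active_reaction_set

logger = logging.getLogger(__name__)

MAX_ITERATIONS = 1000
_SUPP_TOL = 1e-8

__all__ = ["ExtractionResult", "BlockedCoreError", "fastcore_extract", "build_context_model"]


class BlockedCoreError(RuntimeError):
    """Raised when core reactions cannot carry flux in the input model."""

    def __init__(self, blocked: set[str]):
        self.blocked = set(blocked)
        super().__init__(
            f"core contains blocked reactions: {sorted(self.blocked)}"
        )


@dataclass
class ExtractionResult:
    kept_reactions: set[str]
    submodel: MetabolicModel
    core: set[str]
    epsilon: float


class _FastcoreProblem:
    def __init__(self, model: MetabolicModel, epsilon: float):
        self.prob = SteadyStateLp(model)
        self.epsilon = epsilon
        self.lb = self.prob.lb.copy()
        self.ub = self.prob.ub.copy()
        self.index = self.prob.index
        self.rids = self.prob.reaction_ids

    def flip(self, rids: set[str]) -> None:
        for rid in rids:
            j = self.index[rid]
            self.lb[j], self.ub[j] = -self.ub[j], -self.lb[j]

    def lp7(self, J: list[str]) -> np.ndarray | None:
        """Maximise the number of J reactions with flux >= epsilon."""
        prob, eps = self.prob, self.epsilon
        n, k = prob.n, len(J)
        if k == 0:
            return np.zeros(n)
        # variables: v (n) then z (k); maximise sum z; z_j - v_j <= 0
        A_ub = np.zeros((k, n + k))
        for row, rid in enumerate(J):
            A_ub[row, prob.index[rid]] = -1.0
            A_ub[row, n + row] = 1.0
        c = np.concatenate([np.zeros(n), np.ones(k)])
        res = prob.solve(
            c,
            maximize=True,
            lb=self.lb,
            ub=self.ub,
            A_ub=A_ub,
            b_ub=np.zeros(k),
            extra_cols=k,
            extra_bounds=[(0.0, eps)] * k,
        )
        if res.status != "optimal":
            return None
        return res.x[:n]

    def lp10(self, K: list[str], P: list[str]) -> np.ndarray | None:
        """Minimal-L1 support over P subject to v_k >= epsilon for k in K."""
        prob, eps = self.prob, self.epsilon
        n, p = prob.n, len(P)
        lb = self.lb.copy()
        ub = self.ub.copy()
        for rid in K:
            j = prob.index[rid]
            lb[j] = max(lb[j], eps)
        if p == 0:
            res = prob.solve(np.zeros(n), maximize=False, lb=lb, ub=ub)
            return res.x if res.status == "optimal" else None
        big = float(np.max(np.abs(np.concatenate([self.lb, self.ub])))) or 1.0
        A_ub = np.zeros((2 * p, n + p))
        for row, rid in enumerate(P):
            j = prob.index[rid]
            A_ub[row, j] = 1.0
            A_ub[row, n + row] = -1.0
            A_ub[p + row, j] = -1.0
            A_ub[p + row, n + row] = -1.0
        c = np.concatenate([np.zeros(n), np.ones(p)])
        res = prob.solve(
            c,
            maximize=False,
            lb=lb,
            ub=ub,
            A_ub=A_ub,
            b_ub=np.zeros(2 * p),
            extra_cols=p,
            extra_bounds=[(0.0, big)] * p,
        )
        if res.status != "optimal":
            return None
        return res.x[:n]

    def support(self, v: np.ndarray) -> set[str]:
        return {rid for rid, x in zip(self.rids, v) if abs(x) > _SUPP_TOL}

    def reached(self, v: np.ndarray, J: list[str]) -> set[str]:
        tol = 0.99 * self.epsilon
        return {rid for rid in J if v[self.index[rid]] >= tol}

    def find_sparse_mode(self, J: list[str], P: list[str]) -> set[str]:
        v = self.lp7(J)
        if v is None:
            return set()
        K = sorted(self.reached(v, J))
        if not K:
            return set()
        v = self.lp10(K, P)
        if v is None:
            return set()
        return self.support(v)


def fastcore_extract(
    model: MetabolicModel,
    core_set: set[str],
    epsilon: float = DEFAULT_EPSILON,
) -> ExtractionResult:
    """Extract a compact flux-consistent submodel containing the core.

    The input model must itself be flux-consistent (run
    :func:`endogem.lp_analysis.consistent_reactions` first); the biomass
    objective is force-included in the core.  Raises
    :class:`BlockedCoreError` if a core reaction cannot carry flux.
    """
    core = set(core_set)
    unknown = core - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"core contains unknown reactions: {sorted(unknown)}")
    if model.objective_reaction_id:
        core.add(model.objective_reaction_id)

    fc = _FastcoreProblem(model, epsilon)
    all_rxns = set(fc.rids)
    irreversible = {r.id for r in model.reactions if r.lower_bound >= 0}

    J = sorted(core & irreversible)
    A = fc.find_sparse_mode(J, sorted(all_rxns - core))
    blocked_irrev = set(J) - A
    if blocked_irrev:
        raise BlockedCoreError(blocked_irrev)

    J = sorted(core - A)
    flipped = False
    singleton = False
    for _ in range(MAX_ITERATIONS):
        if not J:
            break
        P = sorted(all_rxns - core - A)
        Jw = [J[0]] if singleton else J
        supp = fc.find_sparse_mode(Jw, P)
        A |= supp
        if set(J) & A:
            J = sorted(set(J) - A)
            flipped = False
            singleton = False
            continue
        rev_members = set(Jw) - irreversible
        if flipped or not rev_members:
            if singleton:
                raise BlockedCoreError(set(Jw))
            singleton = True
            flipped = False
        else:
            fc.flip(rev_members)
            flipped = True
    else:
        raise RuntimeError("FASTCORE did not converge within the iteration cap")

    kept = set(A) | core
    submodel = model.subnetwork(sorted(kept), model_id=f"{model.id}_context")

    # Guarantee the documented invariant: every kept reaction consistent in the
    # submodel.  Blocked non-core stragglers (support-threshold artefacts) are
    # dropped; a blocked core member would mean extraction failed.
    for _ in range(10):
        cons = consistent_reactions(submodel, epsilon)
        blocked = kept - cons
        if not blocked:
            break
        if blocked & core:
            raise BlockedCoreError(blocked & core)
        kept -= blocked
        submodel = model.subnetwork(sorted(kept), model_id=f"{model.id}_context")
    return ExtractionResult(kept, submodel, core, epsilon)


def build_context_model(
    model: MetabolicModel,
    profile: ExpressionProfile,
    epsilon: float = DEFAULT_EPSILON,
) -> ExtractionResult:
    """Transcriptome-driven extraction: core = GPR-active ∩ flux-consistent.

    The model is first restricted to its flux-consistent part; the core is the
    set of reactions whose GPR is satisfied by the profile's non-absent
    transcripts (unlinked reactions included) intersected with that consistent
    part, plus the biomass objective.
    """
    consistent = consistent_reactions(model, epsilon)
    if model.objective_reaction_id and model.objective_reaction_id not in consistent:
        raise BlockedCoreError({model.objective_reaction_id})
    consistent_model = model.subnetwork(sorted(consistent), model_id=f"{model.id}_consistent")
    active = active_reaction_set(consistent_model, profile)
    core = (active & consistent) | {model.objective_reaction_id}
    return fastcore_extract(consistent_model, core, epsilon)
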