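"""Independent oracles used by the test suite.

Everything here recomputes expected results through a route that does not go
through the package's own implementations: brute-force vertex enumeration of
the flux polytope, direct scipy.linprog calls, exhaustive subset searches,
textbook statistics formulas, and an explicit carbon-atom bookkeeping for the
lactate labelling distributions.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog
from scipy.stats import t as t_dist


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """All feasible points of {S v = 0, lb <= v <= ub} with n-rank(S) bounds tight.

    Every vertex of the polytope appears in the output (non-degenerate
    fixtures); extra feasible non-vertex points are harmless for max/min
    queries because they are feasible too.
    """
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    d = n - rank
    points = []
    for fixed in itertools.combinations(range(n), d):
        free = [j for j in range(n) if j not in fixed]
        for vals in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.zeros(n)
            for j, val in zip(fixed, vals):
                v[j] = val
            if free:
                A = S[:, free]
                b = -S[:, list(fixed)] @ np.asarray(vals)
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free] = sol
            if np.abs(S @ v).max() > tol:
                continue
            if (v < lb - tol).any() or (v > ub + tol).any():
                continue
            points.append(v)
    if not points:
        return np.empty((0, n))
    return np.unique(np.round(np.asarray(points), 9), axis=0)


def lp_flux_extreme(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, j: int, maximize: bool) -> float | None:
    """Direct scipy.linprog solve for min/max of one flux coordinate."""
    c = np.zeros(S.shape[1])
    c[j] = -1.0 if maximize else 1.0
    bounds = [(lo, hi) for lo, hi in zip(lb, ub)]
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status != 0:
        return None
    return -res.fun if maximize else res.fun


def consistent_reactions_oracle(model, epsilon: float) -> set[str]:
    """Per-reaction max-|flux| LP oracle (both senses for reversibles)."""
    S, _, rids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    out = set()
    for j, rid in enumerate(rids):
        hi = lp_flux_extreme(S, lb, ub, j, maximize=True)
        if hi is not None and hi >= epsilon * 0.999:
            out.add(rid)
            continue
        if lb[j] < 0:
            lo = lp_flux_extreme(S, lb, ub, j, maximize=False)
            if lo is not None and lo <= -epsilon * 0.999:
                out.add(rid)
    return out


def fba_oracle(model) -> float:
    """Maximum objective flux over brute-force enumerated polytope points."""
    S, _, rids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    verts = enumerate_vertices(S, lb, ub)
    j = rids.index(model.objective_reaction_id)
    return float(verts[:, j].max())


def fva_oracle(model) -> dict[str, tuple[float, float]]:
    S, _, rids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    verts = enumerate_vertices(S, lb, ub)
    return {rid: (float(verts[:, j].min()), float(verts[:, j].max())) for j, rid in enumerate(rids)}


def reaction_knockout_oracle(model, threshold: float) -> set[str]:
    """Essential reactions by exhaustive single-knockout LP."""
    S, _, rids = model.stoichiometric_matrix()
    lb0, ub0 = model.bounds_arrays()
    j_obj = rids.index(model.objective_reaction_id)
    wt = lp_flux_extreme(S, lb0, ub0, j_obj, maximize=True)
    assert wt is not None and wt > 0
    essential = set()
    for j, rid in enumerate(rids):
        lb, ub = lb0.copy(), ub0.copy()
        lb[j] = ub[j] = 0.0
        ko = lp_flux_extreme(S, lb, ub, j_obj, maximize=True)
        if ko is None or ko < threshold * wt:
            essential.add(rid)
    return essential


def _subnetwork_all_consistent(model, rxn_ids: set[str], epsilon: float) -> bool:
    sub = model.subnetwork(sorted(rxn_ids))
    S, _, rids = sub.stoichiometric_matrix()
    lb, ub = sub.bounds_arrays()
    for j in range(len(rids)):
        hi = lp_flux_extreme(S, lb, ub, j, maximize=True)
        ok = hi is not None and hi >= epsilon * 0.999
        if not ok and lb[j] < 0:
            lo = lp_flux_extreme(S, lb, ub, j, maximize=False)
            ok = lo is not None and lo <= -epsilon * 0.999
        if not ok:
            return False
    return True


def minimal_consistent_superset_size(model, core: set[str], epsilon: float) -> int:
    """Size of the smallest consistent reaction subset containing the core.

    Exhaustive search over non-core subsets in increasing size; feasible only
    for small fixtures (<= ~14 reactions).
    """
    non_core = sorted(set(model.reaction_ids) - core)
    for extra in range(len(non_core) + 1):
        for subset in itertools.combinations(non_core, extra):
            candidate = core | set(subset)
            if _subnetwork_all_consistent(model, candidate, epsilon):
                return len(candidate)
    raise AssertionError("no consistent superset of the core exists")


def two_sample_t_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-tailed two-sample t-test by the textbook formula."""
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    tstat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(tstat), na + nb - 2)
    return float(tstat), float(p)


# ---------------------------------------------------------------------------
# Carbon-atom bookkeeping oracle for 1,2-13C glucose -> lactate
# ---------------------------------------------------------------------------
#
# Glucose carbons are represented by name ("C1".."C6"); the tracer marks a
# subset as labelled.  Pathways are expressed as explicit lists of product
# molecules, each a tuple of source-carbon names, and lactate label counts are
# tallied at the end.  This enumeration is deliberately written in terms of
# carbon names, not boolean masks, to stay independent of the implementation.

_GLC = ("C1", "C2", "C3", "C4", "C5", "C6")


def _lactate_counts(trioses: list[tuple[str, ...]], labelled: set[str]) -> list[int]:
    return [sum(1 for c in tri if c in labelled) for tri in trioses]


def lactate_distribution_oracle(pathway: str, labelled: set[str] = frozenset({"C1", "C2"})) -> np.ndarray:
    labelled = set(labelled)
    if pathway == "glycolysis":
        # FBP cleavage: C1-C2-C3 (via DHAP, order reversed) and C4-C5-C6.
        trioses = [("C3", "C2", "C1"), ("C4", "C5", "C6")]
    elif pathway == "oxppp":
        # 3 glucose lose C1 as CO2 -> three pentoses P = (C2, C3, C4, C5, C6).
        P = _GLC[1:]
        # TK1: Xu5P + R5P -> S7P + GAP
        s7p = (P[0], P[1], P[0], P[1], P[2], P[3], P[4])
        gap1 = (P[2], P[3], P[4])
        # TA: S7P + GAP -> F6P + E4P
        f6p1 = s7p[0:3] + gap1
        e4p = s7p[3:7]
        # TK2: Xu5P + E4P -> F6P + GAP
        f6p2 = (P[0], P[1]) + e4p
        gap2 = (P[2], P[3], P[4])
        trioses = [
            (f6p1[2], f6p1[1], f6p1[0]),
            f6p1[3:6],
            (f6p2[2], f6p2[1], f6p2[0]),
            f6p2[3:6],
            gap2,
        ]
    else:
        raise ValueError(pathway)
    counts = _lactate_counts(trioses, labelled)
    dist = np.zeros(4)
    for k in counts:
        dist[k] += 1
    return dist / dist.sum()
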