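"""Random sampling of the steady-state flux polytope.

Artificially-centered hit-and-run (ACHR): warmup points are the FVA extreme
solutions (two per reaction), directions are drawn as the difference between a
random warmup point and the running centre, and the step length is uniform on
the feasible chord.  Because every warmup point satisfies S v = 0 and moves are
affine combinations of such points, all samples stay in the null space of S to
solver precision.

Sampled exchange fluxes summarised per reaction (mean/min/max and a
secretion/uptake direction call) feed the patient-model bound derivation and
the biomarker direction tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lp import SteadyStateLp
from .lp_analysis import InfeasibleModelError, fva
from .model_io import MetabolicModel

DEFAULT_N_SAMPLES = 2000
DEFAULT_THINNING = 100
DIRECTION_TOLERANCE = 1e-6

__all__ = [
    "FluxSample",
    "ExchangeSummary",
    "sample_fluxes",
    "summarize_exchanges",
    "DEFAULT_N_SAMPLES",
    "DEFAULT_THINNING",
    "DIRECTION_TOLERANCE",
]


@dataclass
class FluxSample:
    model_id: str
    reaction_ids: list[str]
    points: np.ndarray  # n_samples x n_reactions
    seed: int
    method: str = "achr"

    def column(self, rid: str) -> np.ndarray:
        return self.points[:, self.reaction_ids.index(rid)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=self.reaction_ids)


@dataclass
class ExchangeSummary:
    stats: pd.DataFrame  # index: exchange reaction id; columns mean,min,max,direction
    tolerance: float = DIRECTION_TOLERANCE

    def direction(self, rid: str) -> str:
        return str(self.stats.loc[rid, "direction"])

    def mean(self, rid: str) -> float:
        return float(self.stats.loc[rid, "mean"])

    def bounds(self, rid: str) -> tuple[float, float]:
        return float(self.stats.loc[rid, "min"]), float(self.stats.loc[rid, "max"])


def sample_fluxes(
    model: MetabolicModel,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    thinning: int = DEFAULT_THINNING,
) -> FluxSample:
    """Sample the flux polytope with seeded, reproducible ACHR.

    Degenerate polytopes (all bounds pinned) return the single feasible point
    repeated; infeasible models raise :class:`InfeasibleModelError`.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    prob = SteadyStateLp(model)
    feas = prob.feasible_point()
    if feas.status != "optimal":
        raise InfeasibleModelError(f"cannot sample: model is {feas.status}")

    lb, ub = prob.lb, prob.ub
    rng = np.random.default_rng(seed)

    var = fva(model, fraction_of_optimum=0.0)
    warmup = []
    probe = SteadyStateLp(model)
    for rid in prob.reaction_ids:
        c = probe.objective_vector({rid: 1.0})
        for maximize in (False, True):
            res = probe.solve(c, maximize=maximize)
            if res.status == "optimal":
                warmup.append(res.x)
    W = np.unique(np.round(np.asarray(warmup), 12), axis=0)
    if W.shape[0] == 1 or np.all(
        np.ptp(np.asarray([var.ranges[r] for r in prob.reaction_ids]), axis=1) < 1e-12
    ):
        point = W[0]
        return FluxSample(model.id, list(prob.reaction_ids), np.tile(point, (n_samples, 1)), seed)

    center = W.mean(axis=0)
    x = center.copy()
    samples = np.empty((n_samples, prob.n))
    n_recorded = 0
    n_accum = W.shape[0]
    max_iter = n_samples * thinning * 10
    it = 0
    while n_recorded < n_samples and it < max_iter:
        it += 1
        w = W[rng.integers(W.shape[0])]
        d = w - center
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            continue
        d = d / nrm
        active = np.abs(d) > 1e-12
        if not active.any():
            continue
        lo_steps = (lb[active] - x[active]) / d[active]
        hi_steps = (ub[active] - x[active]) / d[active]
        t_lo = np.minimum(lo_steps, hi_steps).max()
        t_hi = np.maximum(lo_steps, hi_steps).min()
        if t_hi - t_lo < 1e-12:
            continue
        t = rng.uniform(t_lo, t_hi)
        x = np.clip(x + t * d, lb, ub)
        center = (center * n_accum + x) / (n_accum + 1)
        n_accum += 1
        if it % thinning == 0:
            samples[n_recorded] = x
            n_recorded += 1
    if n_recorded < n_samples:  # ill-conditioned chain; pad with current point
        samples[n_recorded:] = x
    return FluxSample(model.id, list(prob.reaction_ids), samples, seed)


def summarize_exchanges(
    sample: FluxSample,
    exchange_ids: list[str],
    tolerance: float = DIRECTION_TOLERANCE,
) -> ExchangeSummary:
    """Per-exchange mean/min/max over samples and a direction call.

    Direction is ``secretion`` when the sample mean exceeds the tolerance,
    ``uptake`` when below its negative, else ``none``.
    """
    missing = set(exchange_ids) - set(sample.reaction_ids)
    if missing:
        raise KeyError(f"exchange ids not in sample: {sorted(missing)}")
    rows = []
    for rid in exchange_ids:
        col = sample.column(rid)
        mean = float(col.mean())
        direction = "secretion" if mean > tolerance else "uptake" if mean < -tolerance else "none"
        rows.append(
            {"reaction_id": rid, "mean": mean, "min": float(col.min()), "max": float(col.max()), "direction": direction}
        )
    stats = pd.DataFrame(rows).set_index("reaction_id")
    return ExchangeSummary(stats, tolerance)
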