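"""Bespoke constraint-integration rules for context-specific models.

Four kinds of experimental information are turned into flux bounds:

1. **Transcript regulation** — case/reference expression ratios with a cutoff
   (default 1.5) classify genes as up-, down-, or unregulated; bounds of
   reactions linked to regulated genes are scaled by 2 (up) or 0.5 (down).
2. **Exchange metabolomics** — measured mean uptake/secretion rates become
   exchange-bound intervals 10% above and below the mean; infeasibility
   afterwards is repaired with the minimal exchange relaxation in
   :mod:`endogem.lp_analysis`.
3. **Isotope-derived pathway split** — a linear coupling row forces the
   glycolysis share of glucose catabolism, v_gly / (v_gly + v_ppp), to the
   fraction estimated from 1,2-13C lactate labelling.
4. **Patient plasma fold changes** — sampled exchange ranges of the base
   (LPS/IFNg) model become survivor-model bounds (0-100 where the range is
   degenerate at zero), and plasma metabolite fold changes scale the survivor
   bounds to give the non-survivor model.

Sign convention throughout: exchange flux > 0 is secretion, < 0 uptake.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model_io import Metabolite, MetabolicModel
from .sampling import ExchangeSummary

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 1.5
UP_FACTOR = 2.0
DOWN_FACTOR = 0.5
DEFAULT_HALFWIDTH = 0.10
DEFAULT_ZERO_BOUNDS = (0.0, 100.0)

__all__ = [
    "RegulationCall",
    "ExchangeMeasurementSet",
    "FoldChangeTable",
    "classify_regulation",
    "scale_bounds_by_regulation",
    "apply_exchange_measurements",
    "apply_ppp_ratio_constraint",
    "derive_survivor_bounds",
    "derive_nonsurvivor_bounds",
    "apply_bounds",
]


@dataclass
class RegulationCall:
    """Per-gene regulation status (up / down / unchanged) at a given cutoff."""

    status: dict[str, str]
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.cutoff <= 1:
            raise ValueError("regulation cutoff must exceed 1")
        bad = set(self.status.values()) - {"up", "down", "unchanged"}
        if bad:
            raise ValueError(f"unknown regulation states {bad}")

    @property
    def up(self) -> set[str]:
        return {g for g, s in self.status.items() if s == "up"}

    @property
    def down(self) -> set[str]:
        return {g for g, s in self.status.items() if s == "down"}


@dataclass
class ExchangeMeasurementSet:
    """Mean exchange rates per metabolite for one condition (signed)."""

    condition: str
    rates: dict[str, float]  # metabolite id -> mean rate
    replicate_n: int = 3


@dataclass
class FoldChangeTable:
    """Plasma metabolite fold changes (non-survivor over survivor)."""

    fold_changes: dict[str, float]

    def __post_init__(self) -> None:
        bad = {m: fc for m, fc in self.fold_changes.items() if fc <= 0}
        if bad:
            raise ValueError(f"fold changes must be positive: {bad}")


def classify_regulation(
    profile_case,
    profile_ref,
    cutoff: float = DEFAULT_CUTOFF,
) -> RegulationCall:
    """Classify shared genes as up/down/unchanged by the case/reference ratio.

    up iff ratio >= cutoff, down iff ratio <= 1/cutoff; a cutoff above 1
    guarantees the two sets are disjoint.  Genes with a non-positive reference
    value are skipped with a warning.
    """
    if cutoff <= 1:
        raise ValueError("cutoff must exceed 1")
    status: dict[str, str] = {}
    skipped = 0
    for gene in set(profile_case.values) & set(profile_ref.values):
        ref = profile_ref.values[gene]
        if ref <= 0:
            skipped += 1
            continue
        ratio = profile_case.values[gene] / ref
        if ratio >= cutoff:
            status[gene] = "up"
        elif ratio <= 1.0 / cutoff:
            status[gene] = "down"
        else:
            status[gene] = "unchanged"
    if skipped:
        logger.warning("classify_regulation: skipped %d genes with non-positive reference", skipped)
    return RegulationCall(status, cutoff)


def scale_bounds_by_regulation(
    model: MetabolicModel,
    regulation: RegulationCall,
    up_factor: float = UP_FACTOR,
    down_factor: float = DOWN_FACTOR,
    scale_lower: bool = True,
) -> MetabolicModel:
    """Scale reaction bounds by gene regulation (both bounds by default).

    A reaction counts as up-regulated when its GPR contains at least one up
    gene and no down gene (and symmetrically for down); conflicts leave it
    untouched.  Positive factors preserve lb <= ub and reversibility class.
    """
    up, down = regulation.up, regulation.down
    out = model.copy()
    for rxn in out.reactions:
        genes = rxn.gpr.genes()
        if not genes:
            continue
        has_up = bool(genes & up)
        has_down = bool(genes & down)
        if has_up == has_down:  # neither, or conflict
            continue
        factor = up_factor if has_up else down_factor
        rxn.upper_bound *= factor
        if scale_lower:
            rxn.lower_bound *= factor
    return out


def _metabolite_exchange_map(model: MetabolicModel) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for rxn in model.exchange_reactions:
        mid = rxn.exchanged_metabolite()
        if mid in mapping:
            raise ValueError(f"metabolite {mid!r} has multiple exchange reactions")
        mapping[mid] = rxn.id
    return mapping


def apply_exchange_measurements(
    model: MetabolicModel,
    measurements: ExchangeMeasurementSet,
    halfwidth: float = DEFAULT_HALFWIDTH,
    metabolite_map: dict[str, str] | None = None,
) -> MetabolicModel:
    """Constrain exchange bounds to +/- ``halfwidth`` x |mean| around the mean.

    The interval is built with |mean| so uptake (negative) means give valid
    intervals; a zero mean pins the exchange to (0, 0) and is logged.  Any
    resulting infeasibility is left to
    :func:`endogem.lp_analysis.relax_to_feasibility`.
    """
    mapping = metabolite_map or _metabolite_exchange_map(model)
    # keys may be metabolite ids or directly exchange-reaction ids
    resolved: dict[str, str] = {}
    unmapped: list[str] = []
    for key in measurements.rates:
        if key in mapping:
            resolved[key] = mapping[key]
        elif model.has_reaction(key) and model.reaction(key).is_exchange:
            resolved[key] = key
        else:
            unmapped.append(key)
    if unmapped:
        raise KeyError(f"metabolites without an exchange reaction: {sorted(unmapped)}")
    out = model.copy()
    for mid, mean in measurements.rates.items():
        rxn = out.reaction(resolved[mid])
        if mean == 0:
            logger.info("exchange %s pinned to zero (measured mean 0)", rxn.id)
        rxn.lower_bound = mean - halfwidth * abs(mean)
        rxn.upper_bound = mean + halfwidth * abs(mean)
    return out


def apply_ppp_ratio_constraint(
    model: MetabolicModel,
    glycolysis_rxn_id: str,
    oxppp_rxn_id: str,
    fraction_glycolysis: float,
) -> MetabolicModel:
    """Couple glycolysis and oxidative-PPP fluxes to a fixed split.

    Adds the stoichiometric row (1-f) v_gly - f v_ppp = 0 via a pseudo
    metabolite, so v_gly / (v_gly + v_ppp) = f at any steady state with
    positive flux through the pair.
    """
    if not 0 < fraction_glycolysis < 1:
        raise ValueError("fraction_glycolysis must be in the open interval (0, 1)")
    out = model.copy()
    gly = out.reaction(glycolysis_rxn_id)
    ppp = out.reaction(oxppp_rxn_id)
    pseudo = "pseudo_glycolysis_ppp_ratio"
    if pseudo in {m.id for m in out.metabolites}:
        raise ValueError("ratio constraint already applied")
    out.metabolites.append(
        Metabolite(pseudo, "glycolysis/PPP flux-ratio coupling", "pseudo", 0)
    )
    f = fraction_glycolysis
    gly.stoichiometry[pseudo] = 1.0 - f
    ppp.stoichiometry[pseudo] = -f
    out._reindex()
    return out


def derive_survivor_bounds(
    base_summary: ExchangeSummary,
    default: tuple[float, float] = DEFAULT_ZERO_BOUNDS,
    zero_tol: float = 1e-9,
) -> dict[str, tuple[float, float]]:
    """Survivor-model exchange bounds from sampled ranges of the base model.

    Each exchange gets (sampled min, sampled max); ranges degenerate at zero
    get the default (0, 100) bounds.
    """
    bounds: dict[str, tuple[float, float]] = {}
    for rid in base_summary.stats.index:
        lo, hi = base_summary.bounds(rid)
        if abs(lo) <= zero_tol and abs(hi) <= zero_tol:
            bounds[rid] = default
        else:
            bounds[rid] = (lo, hi)
    return bounds


def derive_nonsurvivor_bounds(
    survivor_bounds: dict[str, tuple[float, float]],
    fold_changes: FoldChangeTable,
    exchange_of_metabolite: dict[str, str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Scale survivor bounds by plasma fold changes (magnitudes, sign kept).

    The worked rule: bounds (1, 2) with fold change 5 become (5, 10); a
    negative interval (-2, -1) becomes (-10, -5).  Metabolites without a fold
    change keep the survivor bounds; fold change 1 is the identity.
    """
    fc_by_exchange: dict[str, float] = {}
    for mid, fc in fold_changes.fold_changes.items():
        rid = (exchange_of_metabolite or {}).get(mid, mid)
        fc_by_exchange[rid] = fc
    out: dict[str, tuple[float, float]] = {}
    for rid, (lo, hi) in survivor_bounds.items():
        fc = fc_by_exchange.get(rid)
        if fc is None:
            out[rid] = (lo, hi)
            continue
        scaled = sorted((lo * fc, hi * fc))
        out[rid] = (scaled[0], scaled[1])
    return out


def apply_bounds(
    model: MetabolicModel, bounds: dict[str, tuple[float, float]]
) -> MetabolicModel:
    """Return a copy with the given reaction bounds applied."""
    out = model.copy()
    for rid, (lo, hi) in bounds.items():
        rxn = out.reaction(rid)
        rxn.lower_bound = lo
        rxn.upper_bound = hi
    return out
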