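"""Synthetic toy network and omics generators with known ground truth.

The toy network is a ~60-reaction, lumped-pathway stand-in for a genome-scale
endothelial reconstruction: exchanges and transporters for glucose, palmitate,
glutamine, oxygen, lactate, pyruvate, succinate, inosine, taurine, arginine and
tryptophan; lumped glycolysis (glc -> 2 pyr) and single-pass oxidative PPP
(3 glc -> 3 CO2 + 5 pyr); pyruvate dehydrogenase, a lumped TCA/oxidation sink,
palmitate beta-oxidation (1 palmitate -> 8 acetyl-CoA); synthesis and exchange
of the six endothelial-injury biomarkers (NO, L-kynurenine,
5-methoxy-tryptophan, sphingosine-1-phosphate, prostaglandin D2, GABA); and a
biomass reaction draining acetyl-CoA, a nucleotide precursor, an amino-acid
pool and a lipid pool.  Every reaction carries a small GPR over toy genes so
transcript-driven extraction, bound scaling, and essentiality have gene-level
structure to act on.  The default network is flux-consistent and
biomass-feasible by construction.

The omics generators plant known signal (regulated gene sets, true exchange
rates, patient fold changes) with seeded noise, and return the planted truth
alongside the data so pipeline recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .context_builder import FoldChangeTable, ExchangeMeasurementSet
from .lp import SteadyStateLp
from .model_io import (
    ABSENT,
    PRESENT,
    ExpressionProfile,
    Gpr,
    MetabolicModel,
    Metabolite,
    Reaction,
)

BIOMARKER_EXCHANGES = ["EX_no", "EX_kyn", "EX_mtrp", "EX_s1p", "EX_pgd2", "EX_gaba"]

DEFAULT_UPTAKE_BOUNDS = {
    "glc": 10.0,
    "palm": 2.0,
    "gln": 5.0,
    "o2": 20.0,
    "tau": 1.0,
    "arg": 1.0,
    "trp": 1.0,
    "mtrp": 1.0,
    "pgd2": 1.0,
    "gaba": 1.0,
}

__all__ = [
    "ToyNetworkConfig",
    "GroundTruth",
    "BIOMARKER_EXCHANGES",
    "DEFAULT_UPTAKE_BOUNDS",
    "build_toy_network",
    "simulate_expression",
    "simulate_exchange_measurements",
    "simulate_patient_fold_changes",
]


@dataclass
class ToyNetworkConfig:
    include_redundant_paths: bool = True
    uptake_bounds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_UPTAKE_BOUNDS))
    biomarkers: list[str] = field(default_factory=lambda: list(BIOMARKER_EXCHANGES))
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted signal of the synthetic generators, for recovery checks."""

    up_genes: set[str] = field(default_factory=set)
    down_genes: set[str] = field(default_factory=set)
    exchange_means: dict[str, dict[str, float]] = field(default_factory=dict)
    pathway_fractions: dict[str, float] = field(default_factory=dict)
    fold_changes: dict[str, float] = field(default_factory=dict)
    expected_direction_flips: dict[str, tuple[str, str]] = field(default_factory=dict)


def _mets() -> list[Metabolite]:
    carbons = {
        "glc": 6, "palm": 16, "gln": 5, "o2": 0, "pyr": 3, "lac": 3, "accoa": 2,
        "succ": 4, "glu": 5, "aa": 5, "nuc": 10, "lipid": 18, "ino": 10, "tau": 2,
        "arg": 6, "trp": 11, "co2": 1, "no": 0, "kyn": 10, "mtrp": 12, "s1p": 18,
        "pgd2": 20, "gaba": 4,
    }
    extracellular = [
        "glc", "palm", "gln", "o2", "lac", "pyr", "succ", "ino", "tau", "arg",
        "trp", "co2", "no", "kyn", "mtrp", "s1p", "pgd2", "gaba",
    ]
    cytosolic = list(carbons)
    mets = [Metabolite(f"{m}_e", m, "e", carbons[m]) for m in extracellular]
    mets += [Metabolite(f"{m}_c", m, "c", carbons[m]) for m in cytosolic]
    return mets


def build_toy_network(config: ToyNetworkConfig | None = None) -> MetabolicModel:
    """Build the lumped endothelial-like toy network (deterministic)."""
    cfg = config or ToyNetworkConfig()
    up = {**DEFAULT_UPTAKE_BOUNDS, **cfg.uptake_bounds}
    rxns: list[Reaction] = []

    def ex(met: str, lb: float, ub: float) -> None:
        rxns.append(
            Reaction(
                f"EX_{met}", {f"{met}_e": -1.0}, lb, ub,
                Gpr(), "Exchange", "Exchange", is_exchange=True,
            )
        )

    def rx(rid, stoich, lb, ub, gpr, subsystem, super_subsystem) -> None:
        rxns.append(Reaction(rid, stoich, lb, ub, Gpr.parse(gpr), subsystem, super_subsystem))

    # Exchanges: positive flux = secretion, negative = uptake.
    for met in ("glc", "palm", "gln", "o2", "tau", "arg", "trp"):
        ex(met, -up[met], 0.0)
    for met in ("lac", "pyr", "succ", "ino", "co2", "no", "kyn", "s1p"):
        ex(met, 0.0, 1000.0)
    for met in ("mtrp", "pgd2", "gaba"):
        ex(met, -up[met], 1000.0)

    # Transporters.
    uptake_t = ("glc", "palm", "gln", "o2", "tau", "arg", "trp")
    secrete_t = ("lac", "pyr", "succ", "ino", "co2", "no", "kyn", "s1p")
    both_t = ("mtrp", "pgd2", "gaba")
    for met in uptake_t:
        rx(f"T_{met}", {f"{met}_e": -1.0, f"{met}_c": 1.0}, 0.0, 1000.0,
           "", "Extracellular transport", "Transport")
    for met in secrete_t:
        rx(f"T_{met}", {f"{met}_c": -1.0, f"{met}_e": 1.0}, 0.0, 1000.0,
           "", "Extracellular transport", "Transport")
    for met in both_t:
        rx(f"T_{met}", {f"{met}_c": -1.0, f"{met}_e": 1.0}, -1000.0, 1000.0,
           "", "Extracellular transport", "Transport")

    # Central carbon metabolism (lumped).
    rx("GLYC", {"glc_c": -1.0, "pyr_c": 2.0}, 0.0, 1000.0,
       "(g_glyc1 and g_glyc2) or g_glyc3", "Glycolysis", "Carbohydrate")
    rx("OXPPP", {"glc_c": -3.0, "co2_c": 3.0, "pyr_c": 5.0}, 0.0, 1000.0,
       "g_ppp1", "Pentose phosphate pathway", "Carbohydrate")
    rx("LDH", {"pyr_c": -1.0, "lac_c": 1.0}, -1000.0, 1000.0,
       "g_ldh1 or g_ldh2", "Glycolysis", "Carbohydrate")
    rx("PDH", {"pyr_c": -1.0, "accoa_c": 1.0, "co2_c": 1.0}, 0.0, 1000.0,
       "g_pdh1 and g_pdh2", "Pyruvate metabolism", "Energy")
    rx("TCA", {"accoa_c": -1.0, "o2_c": -2.0, "co2_c": 2.0}, 0.0, 1000.0,
       "g_tca1", "Citric acid cycle", "Energy")
    rx("SUCCS", {"accoa_c": -2.0, "succ_c": 1.0}, 0.0, 1000.0,
       "g_tca2", "Citric acid cycle", "Energy")
    rx("BOX", {"palm_c": -1.0, "o2_c": -7.0, "accoa_c": 8.0}, 0.0, 1000.0,
       "g_box1 and g_box2", "Fatty acid oxidation", "Lipid")

    # Nitrogen and amino-acid metabolism.
    rx("GLNU", {"gln_c": -1.0, "glu_c": 1.0}, 0.0, 1000.0,
       "g_gln1", "Glutamate metabolism", "Amino acid")
    rx("GLUDC", {"glu_c": -1.0, "gaba_c": 1.0, "co2_c": 1.0}, 0.0, 1000.0,
       "g_gaba1", "Glutamate metabolism", "Amino acid")
    rx("GABADEG", {"gaba_c": -1.0, "succ_c": 1.0}, 0.0, 1000.0,
       "g_gaba2", "Glutamate metabolism", "Amino acid")
    rx("AAS", {"glu_c": -1.0, "aa_c": 1.0}, 0.0, 1000.0,
       "g_aa1", "Amino acid synthesis", "Amino acid")
    rx("TAUU", {"tau_c": -1.0, "aa_c": 1.0}, 0.0, 1000.0,
       "g_tau1", "Taurine metabolism", "Amino acid")

    # Biosynthetic pools and biomass precursors.
    rx("NUCS", {"accoa_c": -2.0, "gln_c": -1.0, "nuc_c": 1.0}, 0.0, 1000.0,
       "g_nuc1 and g_nuc2", "Nucleotide synthesis", "Nucleotide")
    rx("INOS", {"nuc_c": -1.0, "ino_c": 1.0}, 0.0, 1000.0,
       "g_nuc3", "Nucleotide synthesis", "Nucleotide")
    rx("LIPS", {"accoa_c": -4.0, "lipid_c": 1.0}, 0.0, 1000.0,
       "g_lip1", "Lipid synthesis", "Lipid")

    # Biomarker synthesis and catabolism.
    rx("NOS", {"arg_c": -1.0, "o2_c": -1.0, "no_c": 1.0}, 0.0, 1000.0,
       "g_no1", "Arginine metabolism", "Amino acid")
    rx("IDO", {"trp_c": -1.0, "o2_c": -1.0, "kyn_c": 1.0}, 0.0, 1000.0,
       "g_kyn1", "Tryptophan metabolism", "Amino acid")
    rx("MTPS", {"trp_c": -1.0, "mtrp_c": 1.0}, 0.0, 1000.0,
       "g_mtrp1", "Tryptophan metabolism", "Amino acid")
    rx("MTRPDEG", {"mtrp_c": -1.0, "o2_c": -1.0, "co2_c": 1.0}, 0.0, 1000.0,
       "g_mtrp2", "Tryptophan metabolism", "Amino acid")
    rx("SPHS", {"palm_c": -1.0, "aa_c": -1.0, "s1p_c": 1.0}, 0.0, 1000.0,
       "g_s1p1", "Sphingolipid metabolism", "Lipid")
    rx("PGDS", {"accoa_c": -1.0, "o2_c": -2.0, "pgd2_c": 1.0}, 0.0, 1000.0,
       "g_pgd1", "Eicosanoid metabolism", "Lipid")
    rx("PGD2DEG", {"pgd2_c": -1.0, "co2_c": 1.0}, 0.0, 1000.0,
       "g_pgd2", "Eicosanoid metabolism", "Lipid")

    if cfg.include_redundant_paths:
        rx("AAS2", {"gln_c": -1.0, "aa_c": 1.0}, 0.0, 1000.0,
           "g_aa2", "Amino acid synthesis", "Amino acid")

    rx("BIOMASS", {"accoa_c": -1.0, "nuc_c": -1.0, "aa_c": -1.0, "lipid_c": -1.0},
       0.0, 1000.0, "", "Biomass", "Biomass")

    genes = {g for r in rxns for g in r.gpr.genes()}
    model = MetabolicModel("toy_endothelial", _mets(), rxns, genes, "BIOMASS")
    model.validate()

    from .lp_analysis import fba  # deferred: avoid import cycle at module load

    sol = fba(model)
    if sol.status != "optimal" or sol.objective_value is None or sol.objective_value <= 1e-9:
        raise ValueError(
            "toy network configuration makes biomass infeasible "
            f"(FBA status {sol.status})"
        )
    return model


def simulate_expression(
    model: MetabolicModel,
    regulated_gene_fractions: tuple[float, float] = (0.15, 0.15),
    effect_size: float = 2.0,
    seed: int = 0,
    absent_rate: float = 0.1,
    noise_sigma: float = 0.0,
) -> tuple[dict[str, ExpressionProfile], GroundTruth]:
    """Two-condition expression profiles with planted up/down regulation.

    Baseline expression is log-normal; in the treated condition the planted up
    (down) genes are multiplied (divided) by ``effect_size``.  A fraction of
    the unregulated genes is called absent in both conditions; regulated genes
    are always present.  ``effect_size`` 1.0 plants nothing.
    """
    frac_up, frac_down = regulated_gene_fractions
    if not (0 <= frac_up <= 1 and 0 <= frac_down <= 1 and frac_up + frac_down <= 1):
        raise ValueError("regulated gene fractions must lie in [0, 1] and sum to <= 1")
    rng = np.random.default_rng(seed)
    genes = sorted(model.genes)
    n = len(genes)
    baseline = np.exp(rng.normal(np.log(100.0), 1.0, size=n))
    n_up = round(frac_up * n)
    n_down = round(frac_down * n)
    perm = rng.permutation(n)
    up_idx = set(perm[:n_up])
    down_idx = set(perm[n_up : n_up + n_down])
    treated = baseline.copy()
    for i in up_idx:
        treated[i] *= effect_size
    for i in down_idx:
        treated[i] /= effect_size
    if noise_sigma > 0:
        treated = treated * np.exp(rng.normal(0.0, noise_sigma, size=n))
    unregulated = [i for i in range(n) if i not in up_idx and i not in down_idx]
    n_absent = round(absent_rate * len(unregulated))
    absent_idx = set(rng.permutation(unregulated)[:n_absent].tolist()) if n_absent else set()
    calls = {g: (ABSENT if i in absent_idx else PRESENT) for i, g in enumerate(genes)}
    profiles = {
        "control": ExpressionProfile("control", dict(zip(genes, baseline)), dict(calls)),
        "treated": ExpressionProfile("treated", dict(zip(genes, treated)), dict(calls)),
    }
    planted_up = {genes[i] for i in up_idx} if effect_size != 1.0 else set()
    planted_down = {genes[i] for i in down_idx} if effect_size != 1.0 else set()
    truth = GroundTruth(up_genes=planted_up, down_genes=planted_down)
    return profiles, truth


def simulate_exchange_measurements(
    model: MetabolicModel,
    condition_flux_point: dict[str, float],
    cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
    condition: str = "condition",
    metabolites: list[str] | None = None,
) -> tuple[ExchangeMeasurementSet, GroundTruth]:
    """Noisy replicate exchange-rate measurements around a true flux point.

    The flux point must be a feasible steady state of the model (checked to
    1e-6); per metabolite, replicate rates are true rate x (1 + N(0, cv)) and
    the replicate mean is reported.
    """
    prob = SteadyStateLp(model)
    v = np.array([condition_flux_point.get(r, 0.0) for r in prob.reaction_ids])
    resid = np.abs(prob.S @ v).max()
    lb, ub = prob.lb, prob.ub
    if resid > 1e-6 or (v < lb - 1e-6).any() or (v > ub + 1e-6).any():
        raise ValueError("condition_flux_point is not a feasible steady state of the model")
    rng = np.random.default_rng(seed)
    rates: dict[str, float] = {}
    truth_rates: dict[str, float] = {}
    for rxn in model.exchange_reactions:
        mid = rxn.exchanged_metabolite()
        if metabolites is not None and mid not in metabolites:
            continue
        true = condition_flux_point.get(rxn.id, 0.0)
        reps = true * (1.0 + rng.normal(0.0, cv, size=replicates)) if cv > 0 else np.full(replicates, true)
        rates[mid] = float(np.mean(reps))
        truth_rates[mid] = true
    ms = ExchangeMeasurementSet(condition, rates, replicates)
    truth = GroundTruth(exchange_means={condition: truth_rates})
    return ms, truth


def simulate_patient_fold_changes(
    planted: dict[str, float] | None = None,
    seed: int = 0,
    extra_metabolites: list[str] | None = None,
    extra_sigma: float = 0.2,
) -> tuple[FoldChangeTable, GroundTruth]:
    """Plasma fold-change table (non-survivor / survivor) with planted effects.

    ``planted`` maps exchange-reaction or metabolite ids to exact fold changes
    (defaults plant increased NO and L-kynurenine, decreased
    sphingosine-1-phosphate, increased methoxy-tryptophan demand); additional
    metabolites get mild log-normal fold changes around 1.
    """
    rng = np.random.default_rng(seed)
    if planted is None:
        planted = {"EX_no": 2.0, "EX_kyn": 5.0, "EX_s1p": 0.2, "EX_mtrp": 3.0}
    fold_changes = dict(planted)
    for mid in extra_metabolites or []:
        if mid not in fold_changes:
            fold_changes[mid] = float(np.exp(rng.normal(0.0, extra_sigma)))
    truth = GroundTruth(fold_changes=dict(planted))
    return FoldChangeTable(fold_changes), truth
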