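"""Core metabolic-network data model, GPR logic, and SBML/JSON readers and writers.

The central container is :class:`MetabolicModel`: a stoichiometric network with
per-reaction flux bounds, gene-protein-reaction (GPR) boolean rules, subsystem
labels, and a biomass objective.  Sign conventions used throughout the package:

* Flux through a reaction is signed by its written direction.
* An exchange reaction touches exactly one metabolite with coefficient -1, so a
  **positive** exchange flux is *secretion* and a **negative** flux is *uptake*.

GPR rules are infix boolean expressions over gene identifiers with
case-insensitive ``AND`` / ``OR`` and parentheses (RECON style, no negation),
stored as an expression tree.  A reaction with an empty GPR is "unlinked": it is
considered active regardless of transcript calls.

Two serialisations are supported: SBML Level 3 with the FBC v2 package (via
python-libsbml) and a JSON dialect mirroring the same content (schema in
``docs/model_schema.md``), which keeps tests and analysis scripts free of XML.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

PRESENT = "present"
ABSENT = "absent"

__all__ = [
    "PRESENT",
    "ABSENT",
    "Gpr",
    "GprParseError",
    "ModelValidationError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ExpressionProfile",
    "evaluate_gpr",
    "active_reaction_set",
    "load_model",
    "write_model",
    "model_to_json",
    "model_from_json",
    "read_expression_table",
    "write_expression_table",
]


class GprParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR expression trees
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class Gpr:
    """Boolean gene-reaction rule stored as an expression tree.

    ``root`` is ``None`` for the empty rule (always true), or a nested tuple:
    ``("gene", gene_id)`` or ``("and"|"or", (child, child, ...))``.
    """

    root: tuple | None = None

    @classmethod
    def parse(cls, text: str | None) -> "Gpr":
        if text is None or not text.strip():
            return cls(None)
        tokens = _GPR_TOKEN.findall(text)
        node, pos = _parse_or(tokens, 0)
        if pos != len(tokens):
            raise GprParseError(f"trailing tokens in GPR {text!r}")
        return cls(node)

    def evaluate(self, calls: Mapping[str, str | bool]) -> bool:
        """Evaluate against present/absent calls (missing genes are absent)."""
        return _eval_node(self.root, calls)

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        _collect_genes(self.root, out)
        return frozenset(out)

    def is_empty(self) -> bool:
        return self.root is None

    def to_string(self) -> str:
        return _node_to_string(self.root, top=True)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _parse_or(tokens: list[str], pos: int) -> tuple[tuple, int]:
    node, pos = _parse_and(tokens, pos)
    children = [node]
    while pos < len(tokens) and tokens[pos].lower() == "or":
        nxt, pos = _parse_and(tokens, pos + 1)
        children.append(nxt)
    if len(children) == 1:
        return node, pos
    return ("or", tuple(children)), pos


def _parse_and(tokens: list[str], pos: int) -> tuple[tuple, int]:
    node, pos = _parse_atom(tokens, pos)
    children = [node]
    while pos < len(tokens) and tokens[pos].lower() == "and":
        nxt, pos = _parse_atom(tokens, pos + 1)
        children.append(nxt)
    if len(children) == 1:
        return node, pos
    return ("and", tuple(children)), pos


def _parse_atom(tokens: list[str], pos: int) -> tuple[tuple, int]:
    if pos >= len(tokens):
        raise GprParseError("unexpected end of GPR expression")
    tok = tokens[pos]
    if tok == "(":
        node, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise GprParseError("unbalanced parentheses in GPR expression")
        return node, pos + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GprParseError(f"unexpected token {tok!r} in GPR expression")
    return ("gene", tok), pos + 1


def _eval_node(node: tuple | None, calls: Mapping[str, str | bool]) -> bool:
    if node is None:
        return True
    kind = node[0]
    if kind == "gene":
        call = calls.get(node[1], ABSENT)
        if isinstance(call, bool):
            return call
        return call == PRESENT
    if kind == "and":
        return all(_eval_node(c, calls) for c in node[1])
    if kind == "or":
        return any(_eval_node(c, calls) for c in node[1])
    raise GprParseError(f"unknown GPR node kind {kind!r}")


def _collect_genes(node: tuple | None, out: set[str]) -> None:
    if node is None:
        return
    if node[0] == "gene":
        out.add(node[1])
    else:
        for child in node[1]:
            _collect_genes(child, out)


def _node_to_string(node: tuple | None, top: bool = False) -> str:
    if node is None:
        return ""
    if node[0] == "gene":
        return node[1]
    joiner = f" {node[0]} "
    inner = joiner.join(_node_to_string(c) for c in node[1])
    return inner if top else f"({inner})"


def evaluate_gpr(gpr: "Gpr | str | None", calls: Mapping[str, str | bool]) -> bool:
    """Evaluate a GPR rule (tree or string) against present/absent calls.

    AND is true iff all children are true; OR iff any child is true; the empty
    rule is true (unlinked reactions are always available).
    """
    if not isinstance(gpr, Gpr):
        gpr = Gpr.parse(gpr)
    return gpr.evaluate(calls)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    n_carbons: int = 0  # 0 = unknown

    def __post_init__(self) -> None:
        if not self.compartment:
            raise ModelValidationError(f"metabolite {self.id!r}: empty compartment")
        if self.n_carbons < 0:
            raise ModelValidationError(f"metabolite {self.id!r}: negative carbon count")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: Gpr = field(default_factory=Gpr)
    subsystem: str = ""
    super_subsystem: str = ""
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.gpr, str) or self.gpr is None:
            self.gpr = Gpr.parse(self.gpr)
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} above upper "
                f"bound {self.upper_bound}"
            )
        if self.is_exchange:
            if len(self.stoichiometry) != 1 or not math.isclose(
                next(iter(self.stoichiometry.values())), -1.0
            ):
                raise ModelValidationError(
                    f"exchange reaction {self.id!r} must consume exactly one "
                    "metabolite with coefficient -1"
                )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def exchanged_metabolite(self) -> str:
        if not self.is_exchange:
            raise ValueError(f"{self.id} is not an exchange reaction")
        return next(iter(self.stoichiometry))


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds, GPRs, and a biomass objective."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: set[str] = field(default_factory=set)
    objective_reaction_id: str = ""

    def __post_init__(self) -> None:
        self._met_index: dict[str, Metabolite] = {}
        self._rxn_index: dict[str, Reaction] = {}
        self._reindex()

    def _reindex(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- accessors ---------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        return self._met_index[mid]

    def reaction(self, rid: str) -> Reaction:
        return self._rxn_index[rid]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    # -- structure ---------------------------------------------------------
    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S (metabolites x reactions) plus row and column id orders."""
        mids = self.metabolite_ids
        rids = self.reaction_ids
        midx = {m: i for i, m in enumerate(mids)}
        S = np.zeros((len(mids), len(rids)))
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                S[midx[mid], j] = coef
        return S, mids, rids

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "MetabolicModel":
        mets = [Metabolite(m.id, m.name, m.compartment, m.n_carbons) for m in self.metabolites]
        rxns = [
            Reaction(
                r.id,
                dict(r.stoichiometry),
                r.lower_bound,
                r.upper_bound,
                r.gpr,  # Gpr is frozen, safe to share
                r.subsystem,
                r.super_subsystem,
                r.is_exchange,
            )
            for r in self.reactions
        ]
        return MetabolicModel(self.id, mets, rxns, set(self.genes), self.objective_reaction_id)

    def subnetwork(self, reaction_ids: Iterable[str], model_id: str | None = None) -> "MetabolicModel":
        """Restriction to a reaction subset, dropping orphaned metabolites/genes."""
        keep = set(reaction_ids)
        missing = keep - set(self._rxn_index)
        if missing:
            raise KeyError(f"unknown reactions: {sorted(missing)}")
        rxns = [r for r in self.reactions if r.id in keep]
        used_mets = {mid for r in rxns for mid in r.stoichiometry}
        mets = [m for m in self.metabolites if m.id in used_mets]
        genes = {g for r in rxns for g in r.gpr.genes()}
        sub = MetabolicModel(
            model_id or f"{self.id}_sub",
            [Metabolite(m.id, m.name, m.compartment, m.n_carbons) for m in mets],
            [
                Reaction(
                    r.id,
                    dict(r.stoichiometry),
                    r.lower_bound,
                    r.upper_bound,
                    r.gpr,
                    r.subsystem,
                    r.super_subsystem,
                    r.is_exchange,
                )
                for r in rxns
            ],
            genes,
            self.objective_reaction_id if self.objective_reaction_id in keep else "",
        )
        return sub

    def validate(self) -> None:
        """Check structural invariants; raise ModelValidationError on failure."""
        seen_m: set[str] = set()
        for m in self.metabolites:
            if m.id in seen_m:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
        seen_r: set[str] = set()
        for r in self.reactions:
            if r.id in seen_r:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            for mid in r.stoichiometry:
                if mid not in seen_m:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references undeclared metabolite {mid!r}"
                    )
            for g in r.gpr.genes():
                if g not in self.genes:
                    raise ModelValidationError(
                        f"reaction {r.id!r} GPR uses unlisted gene {g!r}"
                    )
        if self.objective_reaction_id and self.objective_reaction_id not in seen_r:
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )


@dataclass
class ExpressionProfile:
    """Per-gene expression values and present/absent calls for one condition."""

    condition: str
    values: dict[str, float]
    calls: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.values) != set(self.calls):
            raise ModelValidationError(
                f"profile {self.condition!r}: values and calls cover different genes"
            )
        bad = {c for c in self.calls.values()} - {PRESENT, ABSENT}
        if bad:
            raise ModelValidationError(f"profile {self.condition!r}: unknown calls {bad}")

    def call(self, gene: str) -> str:
        return self.calls.get(gene, ABSENT)


def active_reaction_set(model: MetabolicModel, profile: ExpressionProfile) -> set[str]:
    """Reactions whose GPR is satisfied by the profile's non-absent transcripts.

    Genes the profile does not cover are treated as absent (conservative); the
    number of uncovered model genes is logged.  Unlinked reactions (empty GPR,
    including exchanges) are always active.
    """
    uncovered = model.genes - set(profile.calls)
    if uncovered:
        logger.warning(
            "profile %s misses %d model genes (treated as absent)",
            profile.condition,
            len(uncovered),
        )
    return {r.id for r in model.reactions if r.gpr.evaluate(profile.calls)}


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def model_to_json(model: MetabolicModel) -> str:
    """Serialise to the JSON dialect with canonical key ordering (byte-stable)."""
    doc = {
        "id": model.id,
        "objective": model.objective_reaction_id,
        "genes": sorted(model.genes),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "n_carbons": m.n_carbons,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string(),
                "subsystem": r.subsystem,
                "super_subsystem": r.super_subsystem,
                "is_exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def model_from_json(text: str) -> MetabolicModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"malformed model JSON: {exc}") from exc
    try:
        mets = [
            Metabolite(
                d["id"], d.get("name", ""), d.get("compartment", "c"), int(d.get("n_carbons", 0))
            )
            for d in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                d["id"],
                {k: float(v) for k, v in d["stoichiometry"].items()},
                float(d["lower_bound"]),
                float(d["upper_bound"]),
                Gpr.parse(d.get("gpr", "")),
                d.get("subsystem", ""),
                d.get("super_subsystem", ""),
                bool(d.get("is_exchange", False)),
            )
            for d in doc["reactions"]
        ]
        model = MetabolicModel(
            doc["id"], mets, rxns, set(doc.get("genes", [])), doc.get("objective", "")
        )
    except KeyError as exc:
        raise ModelValidationError(f"model JSON missing required field {exc}") from exc
    # Genes may be implicit in GPRs for hand-written files.
    for r in model.reactions:
        model.genes.update(r.gpr.genes())
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2
# ---------------------------------------------------------------------------

_SBML_PREFIX_M = "M_"
_SBML_PREFIX_R = "R_"
_SBML_PREFIX_G = "G_"
_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(prefix: str, raw: str) -> str:
    return prefix + _SID_BAD.sub("_", raw)


def _notes_xhtml(entries: Mapping[str, str]) -> str:
    ps = "".join(f"<p>{k}: {v}</p>" for k, v in entries.items() if v)
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{ps}</body>'


def _parse_notes(notes: str | None) -> dict[str, str]:
    out: dict[str, str] = {}
    if not notes:
        return out
    for key, val in re.findall(r"<p>\s*([A-Z_]+)\s*:\s*(.*?)\s*</p>", notes, re.S):
        out[key] = val
    return out


def model_to_sbml(model: MetabolicModel) -> str:
    """Write SBML Level 3 Version 1 with the FBC v2 package."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb = doc.createModel()
    sb.setId(_SID_BAD.sub("_", model.id) or "model")
    sb.setName(model.id)
    fbc = sb.getPlugin("fbc")
    fbc.setStrict(True)

    for comp in sorted({m.compartment for m in model.metabolites}):
        c = sb.createCompartment()
        c.setId(_sid("", comp))
        c.setConstant(True)

    for m in model.metabolites:
        sp = sb.createSpecies()
        sp.setId(_sid(_SBML_PREFIX_M, m.id))
        sp.setName(m.name or m.id)
        sp.setCompartment(_sid("", m.compartment))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)
        if m.n_carbons > 0:
            sp.getPlugin("fbc").setChemicalFormula(f"C{m.n_carbons}")
        sp.setNotes(_notes_xhtml({"ORIGINAL_ID": m.id}))

    gene_ids = {}
    for g in sorted(model.genes):
        gp = fbc.createGeneProduct()
        gid = _sid(_SBML_PREFIX_G, g)
        gp.setId(gid)
        gp.setLabel(g)
        gene_ids[g] = gid

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sb.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions:
        rx = sb.createReaction()
        rx.setId(_sid(_SBML_PREFIX_R, r.id))
        rx.setName(r.id)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        if r.is_exchange:
            rx.setSBOTerm(627)  # exchange reaction
        for mid, coef in r.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(_sid(_SBML_PREFIX_M, mid))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(_bound_param(r.lower_bound))
        rfbc.setUpperFluxBound(_bound_param(r.upper_bound))
        if not r.gpr.is_empty():
            gpa = rfbc.createGeneProductAssociation()
            # The infix parser matches gene products by fbc:label.
            gpa.setAssociation(_gpr_to_association_string(r.gpr.root))
        rx.setNotes(
            _notes_xhtml(
                {
                    "ORIGINAL_ID": r.id,
                    "SUBSYSTEM": r.subsystem,
                    "SUPER_SUBSYSTEM": r.super_subsystem,
                }
            )
        )

    obj = fbc.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fbc.setActiveObjectiveId("obj")
    if model.objective_reaction_id:
        fo = obj.createFluxObjective()
        fo.setReaction(_sid(_SBML_PREFIX_R, model.objective_reaction_id))
        fo.setCoefficient(1.0)

    return libsbml.writeSBMLToString(doc)


def _gpr_to_association_string(node: tuple) -> str:
    if node[0] == "gene":
        return node[1]
    joiner = " and " if node[0] == "and" else " or "
    return "(" + joiner.join(_gpr_to_association_string(c) for c in node[1]) + ")"


def model_from_sbml(text: str) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelValidationError(f"malformed SBML: {err.getMessage().strip()}")
    sb = doc.getModel()
    if sb is None:
        raise ModelValidationError("malformed SBML: no model element")
    fbc = sb.getPlugin("fbc")

    def _orig(notes: str | None, fallback: str) -> str:
        return _parse_notes(notes).get("ORIGINAL_ID", fallback)

    mets: list[Metabolite] = []
    sid_to_mid: dict[str, str] = {}
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        mid = _orig(sp.getNotesString(), sp.getId().removeprefix(_SBML_PREFIX_M))
        n_carbons = 0
        spf = sp.getPlugin("fbc")
        if spf is not None and spf.isSetChemicalFormula():
            m = re.match(r"C(\d+)", spf.getChemicalFormula())
            if m:
                n_carbons = int(m.group(1))
        mets.append(Metabolite(mid, sp.getName() or mid, sp.getCompartment() or "c", n_carbons))
        sid_to_mid[sp.getId()] = mid

    gene_labels: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId().removeprefix(_SBML_PREFIX_G)

    rxns: list[Reaction] = []
    for i in range(sb.getNumReactions()):
        rx = sb.getReaction(i)
        notes = _parse_notes(rx.getNotesString())
        rid = notes.get("ORIGINAL_ID", rx.getId().removeprefix(_SBML_PREFIX_R))
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[sid_to_mid[ref.getSpecies()]] = (
                stoich.get(sid_to_mid[ref.getSpecies()], 0.0) - ref.getStoichiometry()
            )
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[sid_to_mid[ref.getSpecies()]] = (
                stoich.get(sid_to_mid[ref.getSpecies()], 0.0) + ref.getStoichiometry()
            )
        rfbc = rx.getPlugin("fbc")
        lb, ub = -math.inf, math.inf
        if rfbc is not None:
            lbp = sb.getParameter(rfbc.getLowerFluxBound())
            ubp = sb.getParameter(rfbc.getUpperFluxBound())
            if lbp is not None:
                lb = lbp.getValue()
            if ubp is not None:
                ub = ubp.getValue()
        gpr = Gpr()
        if rfbc is not None and rfbc.isSetGeneProductAssociation():
            gpr = Gpr(_association_to_node(rfbc.getGeneProductAssociation().getAssociation(), gene_labels))
        is_exchange = rx.getSBOTerm() == 627
        rxns.append(
            Reaction(
                rid,
                stoich,
                lb,
                ub,
                gpr,
                notes.get("SUBSYSTEM", ""),
                notes.get("SUPER_SUBSYSTEM", ""),
                is_exchange,
            )
        )

    objective_rid = ""
    if fbc is not None and fbc.getActiveObjective() is not None:
        ao = fbc.getActiveObjective()
        if ao.getNumFluxObjectives() > 0:
            sbml_rid = ao.getFluxObjective(0).getReaction()
            rx = sb.getReaction(sbml_rid)
            if rx is not None:
                objective_rid = _parse_notes(rx.getNotesString()).get(
                    "ORIGINAL_ID", sbml_rid.removeprefix(_SBML_PREFIX_R)
                )

    model = MetabolicModel(
        sb.getName() or sb.getId(),
        mets,
        rxns,
        set(gene_labels.values()),
        objective_rid,
    )
    model.validate()
    return model


def _association_to_node(assoc, gene_labels: Mapping[str, str]) -> tuple:
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        return ("gene", gene_labels.get(assoc.getGeneProduct(), assoc.getGeneProduct()))
    if isinstance(assoc, libsbml.FbcAnd):
        return ("and", tuple(_association_to_node(assoc.getAssociation(i), gene_labels) for i in range(assoc.getNumAssociations())))
    if isinstance(assoc, libsbml.FbcOr):
        return ("or", tuple(_association_to_node(assoc.getAssociation(i), gene_labels) for i in range(assoc.getNumAssociations())))
    raise ModelValidationError(f"unsupported GPR association node {type(assoc)}")


# ---------------------------------------------------------------------------
# File-level API
# ---------------------------------------------------------------------------


def load_model(path, fmt: str | None = None) -> MetabolicModel:
    """Load a model from SBML (.xml/.sbml) or the JSON dialect (.json)."""
    path = str(path)
    if fmt is None:
        fmt = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    with open(path) as fh:
        text = fh.read()
    if fmt == "sbml":
        return model_from_sbml(text)
    if fmt == "json":
        return model_from_json(text)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path, fmt: str | None = None) -> None:
    path = str(path)
    if fmt is None:
        fmt = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if fmt == "sbml":
        text = model_to_sbml(model)
    elif fmt == "json":
        text = model_to_json(model)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    with open(path, "w") as fh:
        fh.write(text)


def read_expression_table(path, condition: str | None = None) -> ExpressionProfile:
    """Read a tab-separated expression table with columns gene_id, value, call."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "value", "call"}
    if not required.issubset(df.columns):
        raise ModelValidationError(
            f"expression table {path} must have columns {sorted(required)}"
        )
    values = dict(zip(df["gene_id"].astype(str), df["value"].astype(float)))
    calls = dict(zip(df["gene_id"].astype(str), df["call"].astype(str)))
    return ExpressionProfile(condition or str(path), values, calls)


def write_expression_table(profile: ExpressionProfile, path) -> None:
    import pandas as pd

    genes = sorted(profile.values)
    pd.DataFrame(
        {
            "gene_id": genes,
            "value": [profile.values[g] for g in genes],
            "call": [profile.calls[g] for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)
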