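"""Shared fixtures: the toy endothelial network and small hand-built models."""

from __future__ import annotations

import pytest

from endogem.model_io import MetabolicModel, Metabolite, Reaction
from endogem.synthetic_data import build_toy_network


def _met(mid: str, comp: str = "c", carbons: int = 0) -> Metabolite:
    return Metabolite(mid, mid, comp, carbons)


def make_chain_model() -> MetabolicModel:
    """EX_A (uptake up to 10) -> transport -> A->B -> biomass drain of B."""
    mets = [_met("A_e", "e", 1), _met("A_c"), _met("B_c")]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, -10.0, 0.0, is_exchange=True),
        Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 100.0),
        Reaction("R_AB", {"A_c": -1.0, "B_c": 1.0}, 0.0, 100.0),
        Reaction("BIO", {"B_c": -1.0}, 0.0, 100.0),
    ]
    m = MetabolicModel("chain", mets, rxns, set(), "BIO")
    m.validate()
    return m


def make_branched_model() -> MetabolicModel:
    """Six reactions, two competing drains of A with different caps."""
    mets = [_met("A_e", "e", 1), _met("A_c"), _met("B_c"), _met("C_c")]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, -10.0, 0.0, is_exchange=True),
        Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 20.0),
        Reaction("R_AB", {"A_c": -1.0, "B_c": 1.0}, 0.0, 20.0),
        Reaction("R_AC", {"A_c": -1.0, "C_c": 1.0}, 0.0, 20.0),
        Reaction("D_B", {"B_c": -1.0}, 0.0, 4.0),
        Reaction("D_C", {"C_c": -1.0}, 0.0, 20.0),
    ]
    m = MetabolicModel("branched", mets, rxns, set(), "D_B")
    m.validate()
    return m


def make_deadend_model() -> MetabolicModel:
    """Ten reactions with two planted dead ends (X has no sink, W no source)."""
    mets = [
        _met("A_e", "e", 1), _met("A_c"), _met("B_c"), _met("C_c"),
        _met("X_c"), _met("W_c"), _met("V_c"),
    ]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, -10.0, 0.0, is_exchange=True),
        Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 100.0),
        Reaction("R_AB", {"A_c": -1.0, "B_c": 1.0}, 0.0, 100.0),
        Reaction("R_BC", {"B_c": -1.0, "C_c": 1.0}, 0.0, 100.0),
        Reaction("BIO", {"C_c": -1.0}, 0.0, 100.0),
        Reaction("D_C2", {"C_c": -1.0}, 0.0, 100.0),
        Reaction("DEAD_PROD", {"A_c": -1.0, "X_c": 1.0}, 0.0, 100.0),  # X unconsumed
        Reaction("DEAD_CONS", {"W_c": -1.0, "V_c": 1.0}, 0.0, 100.0),  # W unproduced
        Reaction("D_V", {"V_c": -1.0}, 0.0, 100.0),
        Reaction("R_AC", {"A_c": -1.0, "C_c": 1.0}, 0.0, 100.0),
    ]
    m = MetabolicModel("deadend", mets, rxns, set(), "BIO")
    m.validate()
    return m


def make_twopath_model() -> MetabolicModel:
    """Twelve reactions; biomass reachable via a short or a long alternative path."""
    mets = [
        _met("A_e", "e", 1), _met("A_c"), _met("B_c"), _met("C_c"),
        _met("D_c"), _met("P_c"), _met("E_c"), _met("E_e", "e", 1),
    ]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, -10.0, 0.0, is_exchange=True),
        Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 100.0),
        # short path (2 reactions)
        Reaction("S1", {"A_c": -1.0, "B_c": 1.0}, 0.0, 100.0),
        Reaction("S2", {"B_c": -1.0, "P_c": 1.0}, 0.0, 100.0),
        # long path (3 reactions)
        Reaction("L1", {"A_c": -1.0, "C_c": 1.0}, 0.0, 100.0),
        Reaction("L2", {"C_c": -1.0, "D_c": 1.0}, 0.0, 100.0),
        Reaction("L3", {"D_c": -1.0, "P_c": 1.0}, 0.0, 100.0),
        Reaction("BIO", {"P_c": -1.0}, 0.0, 100.0),
        # consistent side branch
        Reaction("B1", {"A_c": -1.0, "E_c": 1.0}, 0.0, 100.0),
        Reaction("T_E", {"E_c": -1.0, "E_e": 1.0}, 0.0, 100.0),
        Reaction("EX_E", {"E_e": -1.0}, 0.0, 100.0, is_exchange=True),
        Reaction("B2", {"A_c": -1.0, "E_c": 1.0}, 0.0, 100.0),
    ]
    m = MetabolicModel("twopath", mets, rxns, set(), "BIO")
    m.validate()
    return m


@pytest.fixture(scope="session")
def toy_model() -> MetabolicModel:
    return build_toy_network()


@pytest.fixture()
def chain_model() -> MetabolicModel:
    return make_chain_model()


@pytest.fixture()
def branched_model() -> MetabolicModel:
    return make_branched_model()


@pytest.fixture()
def deadend_model() -> MetabolicModel:
    return make_deadend_model()


@pytest.fixture()
def twopath_model() -> MetabolicModel:
    return make_twopath_model()
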