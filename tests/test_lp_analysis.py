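"""FBA, FVA, consistency, essentiality, relaxation, source preference."""

from __future__ import annotations

import numpy as np
import pytest

from endogem.lp_analysis import (
    InfeasibleModelError,
    consistent_reactions,
    essential_entities,
    fba,
    fva,
    max_product_from_source,
    relax_to_feasibility,
)
from endogem.model_io import MetabolicModel, Metabolite, Reaction

from .oracles import (
    consistent_reactions_oracle,
    fba_oracle,
    fva_oracle,
    reaction_knockout_oracle,
)


class TestFba:
    def test_chain_bottleneck(self, chain_model):
        assert fba(chain_model).objective_value == pytest.approx(10.0)

    def test_closed_uptake_gives_zero(self, chain_model):
        chain_model.reaction("EX_A").lower_bound = 0.0
        assert fba(chain_model).objective_value == pytest.approx(0.0)

    def test_matches_vertex_enumeration(self, chain_model, branched_model):
        for model in (chain_model, branched_model):
            assert fba(model).objective_value == pytest.approx(fba_oracle(model), abs=1e-8)

    def test_optimal_solution_satisfies_steady_state_and_bounds(self, toy_model):
        sol = fba(toy_model)
        S, _, rids = toy_model.stoichiometric_matrix()
        v = np.array([sol.fluxes[r] for r in rids])
        lb, ub = toy_model.bounds_arrays()
        assert np.abs(S @ v).max() <= 1e-9
        assert (v >= lb - 1e-9).all() and (v <= ub + 1e-9).all()

    def test_infeasible_status_reported(self, chain_model):
        # force uptake while its only consumer is closed
        chain_model.reaction("EX_A").upper_bound = -5.0
        chain_model.reaction("EX_A").lower_bound = -5.0
        chain_model.reaction("T_A").upper_bound = 1.0
        sol = fba(chain_model)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}


class TestFva:
    def test_pinned_network_collapses(self, chain_model):
        for r in chain_model.reactions:
            v = 3.0 if not r.is_exchange else -3.0
            r.lower_bound = r.upper_bound = v
        res = fva(chain_model)
        for rid, (lo, hi) in res.items():
            assert lo == pytest.approx(hi)

    def test_fraction_one_collapses_chain(self, chain_model):
        res = fva(chain_model, fraction_of_optimum=1.0)
        sol = fba(chain_model)
        for rid, (lo, hi) in res.items():
            assert lo == pytest.approx(hi, abs=1e-7)
            assert lo == pytest.approx(sol.fluxes[rid], abs=1e-7)

    def test_matches_enumerated_extremes(self, branched_model):
        res = fva(branched_model, fraction_of_optimum=0.0)
        oracle = fva_oracle(branched_model)
        for rid, (lo, hi) in res.items():
            assert lo == pytest.approx(oracle[rid][0], abs=1e-7)
            assert hi == pytest.approx(oracle[rid][1], abs=1e-7)

    def test_ranges_contain_fba_flux(self, toy_model):
        res = fva(toy_model, fraction_of_optimum=1.0)
        sol = fba(toy_model)
        for rid, (lo, hi) in res.items():
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6


class TestConsistency:
    def test_dead_end_reactions_blocked(self, deadend_model):
        cons = consistent_reactions(deadend_model, 1e-4)
        blocked = set(deadend_model.reaction_ids) - cons
        assert blocked == {"DEAD_PROD", "DEAD_CONS", "D_V"}

    def test_chain_fully_consistent(self, chain_model):
        assert consistent_reactions(chain_model, 1e-4) == set(chain_model.reaction_ids)

    @pytest.mark.parametrize("fixture", ["deadend_model", "toy_model", "twopath_model"])
    def test_matches_per_reaction_lp_oracle(self, fixture, request):
        model = request.getfixturevalue(fixture)
        assert consistent_reactions(model, 1e-4) == consistent_reactions_oracle(model, 1e-4)

    def test_requires_positive_epsilon(self, chain_model):
        with pytest.raises(ValueError):
            consistent_reactions(chain_model, 0.0)


class TestEssentiality:
    def test_sole_path_gene_essential(self):
        m = MetabolicModel(
            "m",
            [Metabolite("A_e", "A", "e", 1), Metabolite("A_c", "A", "c", 1)],
            [
                Reaction("EX_A", {"A_e": -1.0}, -10.0, 0.0, is_exchange=True),
                Reaction("T", {"A_e": -1.0, "A_c": 1.0}, 0.0, 100.0, "g1"),
                Reaction("BIO", {"A_c": -1.0}, 0.0, 100.0),
            ],
            {"g1"},
            "BIO",
        )
        res = essential_entities(m, "gene")
        assert res.essential == {"g1"}
        assert res.growth_ratio["g1"] == pytest.approx(0.0)

    def test_redundant_or_paths_not_essential(self):
        m = MetabolicModel(
            "m",
            [Metabolite("A_e", "A", "e", 1), Metabolite("A_c", "A", "c", 1)],
            [
                Reaction("EX_A", {"A_e": -1.0}, -10.0, 0.0, is_exchange=True),
                Reaction("T1", {"A_e": -1.0, "A_c": 1.0}, 0.0, 100.0, "g1"),
                Reaction("T2", {"A_e": -1.0, "A_c": 1.0}, 0.0, 100.0, "g2"),
                Reaction("BIO", {"A_c": -1.0}, 0.0, 100.0),
            ],
            {"g1", "g2"},
            "BIO",
        )
        assert essential_entities(m, "gene").essential == set()

    def test_reaction_scan_matches_exhaustive_ko(self, toy_model):
        res = essential_entities(toy_model, "reaction", threshold=0.01)
        assert res.essential == reaction_knockout_oracle(toy_model, 0.01)

    def test_gene_scan_matches_cobra(self, toy_model, tmp_path):
        cobra = pytest.importorskip("cobra")
        from endogem.model_io import write_model

        path = tmp_path / "toy.xml"
        write_model(toy_model, path, fmt="sbml")
        cm = cobra.io.read_sbml_model(str(path))
        cm.solver = "glpk"
        wt = cm.slim_optimize()
        oracle = set()
        for g in cm.genes:
            with cm:
                g.knock_out()
                v = cm.slim_optimize()
                if np.isnan(v) or v < 0.01 * wt:
                    oracle.add(g.id)
        assert essential_entities(toy_model, "gene").essential == oracle

    def test_zero_wild_type_raises(self, chain_model):
        chain_model.reaction("EX_A").lower_bound = 0.0
        with pytest.raises(InfeasibleModelError):
            essential_entities(chain_model, "reaction")

    def test_essential_reactions_truly_block_growth(self, toy_model):
        res = essential_entities(toy_model, "reaction", threshold=0.01)
        wt = fba(toy_model).objective_value
        for rid in res.essential:
            ko = toy_model.copy()
            ko.reaction(rid).lower_bound = 0.0
            ko.reaction(rid).upper_bound = 0.0
            sol = fba(ko)
            obj = sol.objective_value if sol.status == "optimal" else 0.0
            assert obj < 0.01 * wt


class TestRelaxation:
    def _nitrogen_model(self):
        mets = [
            Metabolite("C_e", "C", "e", 1), Metabolite("N_e", "N", "e", 0),
            Metabolite("C_c", "C", "c", 1), Metabolite("N_c", "N", "c", 0),
            Metabolite("B_c", "B", "c", 0),
        ]
        rxns = [
            Reaction("EX_c", {"C_e": -1.0}, -10.0, 0.0, is_exchange=True),
            Reaction("EX_gln", {"N_e": -1.0}, 0.0, 0.0, is_exchange=True),  # closed
            Reaction("T_C", {"C_e": -1.0, "C_c": 1.0}, 0.0, 100.0),
            Reaction("T_N", {"N_e": -1.0, "N_c": 1.0}, 0.0, 100.0),
            Reaction("BIO", {"C_c": -1.0, "N_c": -1.0, "B_c": 1.0}, 1.0, 100.0),
            Reaction("D_B", {"B_c": -1.0}, 0.0, 100.0),
        ]
        return MetabolicModel("nit", mets, rxns, set(), "BIO")

    def test_unique_fix_found(self):
        m = self._nitrogen_model()
        relaxed, rset = relax_to_feasibility(m, ["EX_c", "EX_gln"])
        assert rset == {"EX_gln"}
        assert fba(relaxed).status == "optimal"

    def test_feasible_model_untouched(self, chain_model):
        relaxed, rset = relax_to_feasibility(chain_model, ["EX_A"])
        assert rset == set()
        assert relaxed is chain_model

    def test_two_independent_conflicts_need_two(self):
        m = self._nitrogen_model()
        # close carbon too: now both exchanges must be relaxed
        mets = m.metabolites
        m.reaction("EX_c").lower_bound = 0.0
        relaxed, rset = relax_to_feasibility(m, ["EX_c", "EX_gln"])
        assert rset == {"EX_c", "EX_gln"}
        assert fba(relaxed).status == "optimal"

    def test_hopeless_model_raises(self):
        m = self._nitrogen_model()
        m.reaction("T_N").upper_bound = 0.0  # no candidate relaxation can help
        with pytest.raises(InfeasibleModelError):
            relax_to_feasibility(m, ["EX_c", "EX_gln"])

    def test_elastic_route_agrees_on_small_instance(self):
        m = self._nitrogen_model()
        _, exact = relax_to_feasibility(m, ["EX_c", "EX_gln"])
        _, elastic = relax_to_feasibility(m, ["EX_c", "EX_gln"], max_exact_candidates=0)
        assert elastic == exact


class TestSourcePreference:
    def test_glucose_ceiling(self, toy_model):
        glc_ub = -toy_model.reaction("EX_glc").lower_bound
        assert max_product_from_source(toy_model, "accoa_c", "EX_glc") == pytest.approx(
            2 * glc_ub
        )

    def test_palmitate_ceiling(self, toy_model):
        palm_ub = -toy_model.reaction("EX_palm").lower_bound
        assert max_product_from_source(toy_model, "accoa_c", "EX_palm") == pytest.approx(
            8 * palm_ub
        )

    def test_ratio_follows_hand_stoichiometry(self, toy_model):
        # palmitate uptake 3 -> 24 acetyl-CoA; glucose uptake 10 -> 20: ratio 1.2
        m = toy_model.copy()
        m.reaction("EX_palm").lower_bound = -3.0
        m.reaction("EX_o2").lower_bound = -30.0  # beta-oxidation needs 7 O2/palmitate
        from_palm = max_product_from_source(m, "accoa_c", "EX_palm")
        from_glc = max_product_from_source(m, "accoa_c", "EX_glc")
        assert from_palm / from_glc == pytest.approx(24.0 / 20.0)

    def test_unknown_product_raises(self, toy_model):
        with pytest.raises(KeyError):
            max_product_from_source(toy_model, "nonexistent_c", "EX_glc")
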