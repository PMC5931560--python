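"""Constraint-integration rules: regulation, measurements, ratio, patients."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endogem.context_builder import (
    ExchangeMeasurementSet,
    FoldChangeTable,
    apply_bounds,
    apply_exchange_measurements,
    apply_ppp_ratio_constraint,
    classify_regulation,
    derive_nonsurvivor_bounds,
    derive_survivor_bounds,
    scale_bounds_by_regulation,
)
from endogem.lp_analysis import fba, relax_to_feasibility
from endogem.model_io import ExpressionProfile, PRESENT
from endogem.sampling import sample_fluxes, summarize_exchanges


def _profiles(values_case, values_ref):
    calls = {g: PRESENT for g in values_case}
    return (
        ExpressionProfile("case", dict(values_case), dict(calls)),
        ExpressionProfile("ref", dict(values_ref), {g: PRESENT for g in values_ref}),
    )


class TestClassifyRegulation:
    @pytest.mark.parametrize(
        "ratio,expected", [(2.0, "up"), (1.5, "up"), (1.0, "unchanged"), (0.5, "down")]
    )
    def test_threshold_rule(self, ratio, expected):
        case, ref = _profiles({"g": ratio * 10.0}, {"g": 10.0})
        assert classify_regulation(case, ref, cutoff=1.5).status["g"] == expected

    def test_full_table_matches_elementwise_oracle(self):
        rng = np.random.default_rng(42)
        ref_vals = {f"g{i}": float(rng.uniform(1, 100)) for i in range(100)}
        ratios = {g: float(rng.uniform(0.2, 5.0)) for g in ref_vals}
        case_vals = {g: ref_vals[g] * ratios[g] for g in ref_vals}
        case, ref = _profiles(case_vals, ref_vals)
        reg = classify_regulation(case, ref, cutoff=1.5)
        for g, r in ratios.items():
            expected = "up" if r >= 1.5 else "down" if r <= 1 / 1.5 else "unchanged"
            assert reg.status[g] == expected

    def test_non_positive_reference_skipped(self):
        case, ref = _profiles({"g": 5.0, "h": 5.0}, {"g": 0.0, "h": 1.0})
        reg = classify_regulation(case, ref)
        assert "g" not in reg.status and reg.status["h"] == "up"

    @settings(max_examples=60, derandomize=True)
    @given(
        ratios=st.lists(st.floats(0.01, 100.0), min_size=1, max_size=20),
        cutoff=st.floats(1.0001, 10.0),
    )
    def test_up_and_down_always_disjoint(self, ratios, cutoff):
        ref_vals = {f"g{i}": 10.0 for i in range(len(ratios))}
        case_vals = {f"g{i}": 10.0 * r for i, r in enumerate(ratios)}
        case, ref = _profiles(case_vals, ref_vals)
        reg = classify_regulation(case, ref, cutoff=cutoff)
        assert not (reg.up & reg.down)


class TestScaleBounds:
    def test_paper_factors(self, toy_model):
        from endogem.context_builder import RegulationCall

        m = toy_model.copy()
        m.reaction("NOS").lower_bound, m.reaction("NOS").upper_bound = 0.0, 8.0
        m.reaction("LDH").lower_bound, m.reaction("LDH").upper_bound = -10.0, 10.0
        reg = RegulationCall({"g_no1": "up", "g_ldh1": "down", "g_ldh2": "down"})
        out = scale_bounds_by_regulation(m, reg)
        assert (out.reaction("NOS").lower_bound, out.reaction("NOS").upper_bound) == (0.0, 16.0)
        assert (out.reaction("LDH").lower_bound, out.reaction("LDH").upper_bound) == (-5.0, 5.0)

    def test_unregulated_and_conflicted_untouched(self, toy_model):
        from endogem.context_builder import RegulationCall

        reg = RegulationCall({"g_pdh1": "up", "g_pdh2": "down"})  # conflict on PDH
        out = scale_bounds_by_regulation(toy_model, reg)
        for rid in toy_model.reaction_ids:
            a, b = toy_model.reaction(rid), out.reaction(rid)
            assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)

    def test_bound_order_and_reversibility_preserved(self, toy_model):
        from endogem.context_builder import RegulationCall

        reg = RegulationCall({g: ("up" if i % 2 else "down") for i, g in enumerate(sorted(toy_model.genes))})
        out = scale_bounds_by_regulation(toy_model, reg)
        for a, b in zip(toy_model.reactions, out.reactions):
            assert b.lower_bound <= b.upper_bound
            assert (a.lower_bound < 0) == (b.lower_bound < 0)


class TestExchangeMeasurements:
    @pytest.mark.parametrize(
        "mean,expected",
        [(1.0, (0.9, 1.1)), (-2.0, (-2.2, -1.8)), (0.0, (0.0, 0.0))],
    )
    def test_ten_percent_rule(self, toy_model, mean, expected):
        ms = ExchangeMeasurementSet("c", {"lac_e": mean})
        out = apply_exchange_measurements(toy_model, ms)
        rxn = out.reaction("EX_lac")
        assert (rxn.lower_bound, rxn.upper_bound) == (pytest.approx(expected[0]), pytest.approx(expected[1]))

    def test_unmapped_metabolite_raises(self, toy_model):
        with pytest.raises(KeyError, match="unknown_met"):
            apply_exchange_measurements(toy_model, ExchangeMeasurementSet("c", {"unknown_met": 1.0}))

    def test_measurements_then_relaxation_feasible(self, toy_model):
        # Constrain to a genuine flux point but close glutamine, forcing a
        # minimal relaxation to recover feasibility.
        sol = fba(toy_model)
        rates = {
            r.exchanged_metabolite(): sol.fluxes[r.id] for r in toy_model.exchange_reactions
        }
        rates["gln_e"] = 0.0  # contradiction: biomass needs glutamine
        out = apply_exchange_measurements(toy_model, ExchangeMeasurementSet("c", rates))
        ex_ids = [r.id for r in toy_model.exchange_reactions]
        relaxed, rset = relax_to_feasibility(out, ex_ids)
        assert fba(relaxed).status == "optimal"
        assert rset  # something had to give


class TestPppRatio:
    def test_symmetric_split(self, toy_model):
        m = apply_ppp_ratio_constraint(toy_model, "GLYC", "OXPPP", 0.5)
        s = sample_fluxes(m, n_samples=50, seed=2, thinning=10)
        vg, vp = s.column("GLYC"), s.column("OXPPP")
        assert np.allclose(vg, vp, atol=1e-6)

    def test_measured_fraction_is_enforced(self, toy_model):
        m = apply_ppp_ratio_constraint(toy_model, "GLYC", "OXPPP", 0.68)
        s = sample_fluxes(m, n_samples=50, seed=2, thinning=10)
        vg, vp = s.column("GLYC"), s.column("OXPPP")
        mask = (vg + vp) > 1e-6
        assert np.allclose(vg[mask] / (vg + vp)[mask], 0.68, atol=1e-6)

    def test_extreme_fraction_keeps_biomass_feasible(self, toy_model):
        m = apply_ppp_ratio_constraint(toy_model, "GLYC", "OXPPP", 0.999999)
        sol = fba(m)
        assert sol.status == "optimal" and sol.objective_value > 0
        assert abs(sol.fluxes["OXPPP"]) <= 1e-3 * max(sol.fluxes["GLYC"], 1.0)

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_outside_open_interval_raises(self, toy_model, f):
        with pytest.raises(ValueError):
            apply_ppp_ratio_constraint(toy_model, "GLYC", "OXPPP", f)


class TestPatientBounds:
    def _summary(self, toy_model, pins):
        m = toy_model.copy()
        for rid, (lo, hi) in pins.items():
            m.reaction(rid).lower_bound = lo
            m.reaction(rid).upper_bound = hi
        s = sample_fluxes(m, n_samples=20, seed=4, thinning=5)
        return summarize_exchanges(s, list(pins))

    def test_sampled_ranges_become_bounds(self, toy_model):
        summ = self._summary(toy_model, {"EX_lac": (1.0, 1.0), "EX_glc": (-4.0, -4.0)})
        bounds = derive_survivor_bounds(summ)
        assert bounds["EX_lac"] == (pytest.approx(1.0), pytest.approx(1.0))
        assert bounds["EX_glc"] == (pytest.approx(-4.0), pytest.approx(-4.0))

    def test_zero_range_gets_default(self, toy_model):
        summ = self._summary(toy_model, {"EX_succ": (0.0, 0.0)})
        assert derive_survivor_bounds(summ)["EX_succ"] == (0.0, 100.0)

    @pytest.mark.parametrize(
        "bounds,fc,expected",
        [
            ((1.0, 2.0), 5.0, (5.0, 10.0)),
            ((-2.0, -1.0), 5.0, (-10.0, -5.0)),
            ((1.0, 2.0), 1.0, (1.0, 2.0)),
            ((3.0, 7.0), 0.5, (1.5, 3.5)),
        ],
    )
    def test_fold_change_scaling(self, bounds, fc, expected):
        out = derive_nonsurvivor_bounds({"EX_x": bounds}, FoldChangeTable({"EX_x": fc}))
        assert out["EX_x"] == (pytest.approx(expected[0]), pytest.approx(expected[1]))

    def test_magnitude_scaling_oracle_on_random_intervals(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            lo = float(rng.uniform(-5, 5))
            hi = lo + float(rng.uniform(0, 5))
            fc = float(rng.uniform(0.1, 10))
            out = derive_nonsurvivor_bounds({"e": (lo, hi)}, FoldChangeTable({"e": fc}))
            a, b = out["e"]
            assert a <= b
            assert sorted([abs(a), abs(b)]) == pytest.approx(sorted([abs(lo) * fc, abs(hi) * fc]))

    def test_identity_at_unit_fold_change_everywhere(self):
        bounds = {"e1": (1.0, 2.0), "e2": (-3.0, 0.5)}
        out = derive_nonsurvivor_bounds(bounds, FoldChangeTable({"e1": 1.0, "e2": 1.0}))
        assert out == bounds

    def test_missing_fold_change_keeps_survivor_bounds(self):
        out = derive_nonsurvivor_bounds({"e1": (1.0, 2.0)}, FoldChangeTable({"other": 2.0}))
        assert out["e1"] == (1.0, 2.0)

    def test_non_positive_fold_change_rejected(self):
        with pytest.raises(ValueError):
            FoldChangeTable({"e": 0.0})

    def test_apply_bounds_round_trip(self, toy_model):
        out = apply_bounds(toy_model, {"EX_lac": (0.5, 0.6)})
        assert (out.reaction("EX_lac").lower_bound, out.reaction("EX_lac").upper_bound) == (0.5, 0.6)
        assert toy_model.reaction("EX_lac").lower_bound == 0.0  # original untouched
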