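"""Flux-space comparison: fold changes, t-tests, clustering, biomarkers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from endogem.compare import (
    biomarker_direction_table,
    cluster_changed_reactions,
    compare_models,
)
from endogem.sampling import ExchangeSummary, FluxSample

from .oracles import two_sample_t_oracle


def _sample(points, rids, model_id="m", seed=0):
    return FluxSample(model_id, list(rids), np.asarray(points, dtype=float), seed)


def _summary(means: dict[str, float], tol=1e-6) -> ExchangeSummary:
    rows = [
        {
            "reaction_id": rid,
            "mean": m,
            "min": m - 0.1,
            "max": m + 0.1,
            "direction": "secretion" if m > tol else "uptake" if m < -tol else "none",
        }
        for rid, m in means.items()
    ]
    return ExchangeSummary(pd.DataFrame(rows).set_index("reaction_id"), tol)


class TestCompareModels:
    def test_twofold_mean_selected(self):
        rng = np.random.default_rng(0)
        noise = 0.001 * rng.normal(size=(50, 1))
        a = _sample(1.0 + noise - noise.mean(), ["R"])  # mean exactly 1
        b = _sample(2.0 + noise - noise.mean(), ["R"])  # mean exactly 2
        res = compare_models(a, b, fold_threshold=2.0)
        row = res.table.loc["R"]
        assert row["fold_change"] == pytest.approx(2.0, abs=1e-8)
        assert "R" in res.selected

    def test_equal_means_not_selected(self):
        a = _sample(np.ones((20, 1)), ["R"])
        b = _sample(np.ones((20, 1)), ["R"])
        res = compare_models(a, b)
        assert res.table.loc["R", "fold_change"] == pytest.approx(1.0)
        assert res.selected == set()

    def test_sign_flip_always_selected(self):
        a = _sample(np.full((20, 1), 0.5), ["R"])
        b = _sample(np.full((20, 1), -0.5), ["R"])
        res = compare_models(a, b, fold_threshold=10.0)
        assert res.table.loc["R", "sign_flip"]
        assert "R" in res.selected

    def test_t_and_bonferroni_match_textbook_oracle(self):
        rng = np.random.default_rng(7)
        n_rxn = 50
        rids = [f"R{i:02d}" for i in range(n_rxn)]
        pa = rng.normal(0, 1, size=(30, n_rxn))
        pb = rng.normal(0.3, 1, size=(30, n_rxn))
        res = compare_models(_sample(pa, rids), _sample(pb, rids))
        for j, rid in enumerate(rids):
            t_exp, p_exp = two_sample_t_oracle(pa[:, j], pb[:, j])
            row = res.table.loc[rid]
            assert row["t_statistic"] == pytest.approx(t_exp, rel=1e-9)
            assert row["p_value"] == pytest.approx(p_exp, rel=1e-9)
            assert row["p_bonferroni"] == pytest.approx(min(p_exp * n_rxn, 1.0), rel=1e-9)
            assert row["significant"] == (min(p_exp * n_rxn, 1.0) <= 0.05)

    def test_symmetry_up_to_direction(self):
        rng = np.random.default_rng(3)
        rids = ["R1", "R2", "R3"]
        pa = rng.normal(1, 0.2, size=(25, 3))
        pb = rng.normal(2, 0.2, size=(25, 3))
        ab = compare_models(_sample(pa, rids), _sample(pb, rids))
        ba = compare_models(_sample(pb, rids), _sample(pa, rids))
        assert np.allclose(ab.table["fold_change"], ba.table["fold_change"])
        assert np.allclose(ab.table["p_value"], ba.table["p_value"])
        assert (ab.table["direction"] != ba.table["direction"]).all()

    def test_mismatched_reactions_raise(self):
        a = _sample(np.ones((5, 1)), ["R1"])
        b = _sample(np.ones((5, 1)), ["R2"])
        with pytest.raises(ValueError):
            compare_models(a, b)

    def test_selected_reactions_satisfy_rule(self):
        rng = np.random.default_rng(11)
        rids = [f"R{i}" for i in range(20)]
        pa = rng.normal(0.0, 1.0, size=(40, 20))
        pb = rng.normal(0.5, 1.0, size=(40, 20))
        res = compare_models(_sample(pa, rids), _sample(pb, rids), fold_threshold=2.0)
        for rid in res.selected:
            row = res.table.loc[rid]
            assert row["fold_change"] >= 2.0 or row["sign_flip"]


class TestClustering:
    def test_planted_partition_recovered(self):
        up = np.array([1.0, 2.0, 3.0, 4.0])
        down = up[::-1]
        rows = {f"U{i}": up * (i + 1) for i in range(4)}
        rows |= {f"D{i}": down * (i + 1) for i in range(4)}
        fm = pd.DataFrame(rows).T
        fm.columns = ["control", "ifn", "lps", "both"]
        rep = cluster_changed_reactions(fm, n_clusters=2)
        labels_up = {rep.labels[f"U{i}"] for i in range(4)}
        labels_down = {rep.labels[f"D{i}"] for i in range(4)}
        assert len(labels_up) == 1 and len(labels_down) == 1
        assert labels_up != labels_down

    def test_identical_rows_form_single_cluster(self):
        fm = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (5, 1)), index=[f"R{i}" for i in range(5)])
        rep = cluster_changed_reactions(fm, cut_height=0.5)
        assert set(rep.labels.values()) == {1}

    def test_subsystem_share_normalisation(self):
        fm = pd.DataFrame(
            {"m1": [1, 2, 3, 4], "m2": [4, 3, 2, 1]},
            index=["R1", "R2", "R3", "R4"],
        ).astype(float)
        # super subsystem X has 8 reactions in the model; 4 were selected
        ss = {f"R{i}": "X" for i in range(1, 9)}
        rep = cluster_changed_reactions(fm, n_clusters=2, super_subsystems=ss)
        shares = rep.subsystem_table.groupby("super_subsystem")["share"].sum()
        assert shares["X"] == pytest.approx(4 / 8)

    def test_invariant_to_row_order_and_monotone_transform(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(6, 4))
        fm = pd.DataFrame(base, index=[f"R{i}" for i in range(6)])
        rep1 = cluster_changed_reactions(fm, n_clusters=2)
        shuffled = fm.sample(frac=1.0, random_state=1)
        rep2 = cluster_changed_reactions(shuffled, n_clusters=2)
        assert rep1.labels == rep2.labels
        # strictly increasing per-column transform preserves Spearman distances
        transformed = fm.apply(lambda col: np.exp(col) + col, axis=0)
        rep3 = cluster_changed_reactions(transformed, n_clusters=2)
        assert rep1.labels == rep3.labels

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            cluster_changed_reactions(pd.DataFrame([[1.0, 2.0]], index=["R"]), n_clusters=1)


class TestBiomarkerTable:
    def test_increase_and_direction(self):
        tab = biomarker_direction_table(
            {"ref": _summary({"EX_b": 2.0}), "case": _summary({"EX_b": 3.0})},
            ["EX_b"],
        )
        assert tab.loc["EX_b", "ref_direction"] == "secretion"
        assert tab.loc["EX_b", "case_direction"] == "secretion"
        assert tab.loc["EX_b", "case_level"] == "increase"

    def test_direction_change_reported(self):
        tab = biomarker_direction_table(
            {"ref": _summary({"EX_b": 2.0}), "case": _summary({"EX_b": -1.0})},
            ["EX_b"],
        )
        assert tab.loc["EX_b", "ref_direction"] == "secretion"
        assert tab.loc["EX_b", "case_direction"] == "uptake"
        assert tab.loc["EX_b", "case_level"] == "decrease"

    def test_flip_only_in_combined_model(self):
        summaries = {
            "control": _summary({"EX_b": 1.0}),
            "lps": _summary({"EX_b": 0.5}),
            "ifn": _summary({"EX_b": 0.8}),
            "combined": _summary({"EX_b": -0.4}),
        }
        tab = biomarker_direction_table(summaries, ["EX_b"], reference="control")
        directions = {m: tab.loc["EX_b", f"{m}_direction"] for m in summaries}
        assert directions == {
            "control": "secretion",
            "lps": "secretion",
            "ifn": "secretion",
            "combined": "uptake",
        }

    def test_missing_biomarker_raises(self):
        with pytest.raises(KeyError):
            biomarker_direction_table({"ref": _summary({"EX_b": 1.0})}, ["EX_missing"])
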