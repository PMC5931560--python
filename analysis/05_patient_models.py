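#!/usr/bin/env python
"""Derive sepsis survivor / non-survivor models and compare biomarkers.

Survivor exchange bounds are the sampled min/max of the treated (inflamed)
model, with (0, 100) where a range is degenerate at zero; non-survivor bounds
scale the survivor bounds by the plasma fold changes.  Both patient models are
sampled and the biomarker direction/level table is written to results/.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import endogem as eg  # noqa: E402

RESULTS = ROOT / "results"
SEED = 1


def main(seed: int = SEED) -> None:
    base = eg.load_model(RESULTS / "model_treated.json")
    fold_changes = eg.FoldChangeTable(
        json.loads((RESULTS / "patient_fold_changes.json").read_text())
    )
    ex_ids = [r.id for r in base.exchange_reactions]
    biomarkers = list(eg.BIOMARKER_EXCHANGES)
    candidates = [r for r in ex_ids if r not in biomarkers]

    base_sample = eg.sample_fluxes(base, n_samples=300, seed=seed, thinning=20)
    survivor_bounds = eg.derive_survivor_bounds(eg.summarize_exchanges(base_sample, ex_ids))
    ns_bounds = eg.derive_nonsurvivor_bounds(survivor_bounds, fold_changes)

    survivor = eg.apply_bounds(base, survivor_bounds)
    non_survivor, relaxed = eg.relax_to_feasibility(
        eg.apply_bounds(base, ns_bounds), candidates
    )
    print(f"Survivor bounds from sampling {len(survivor_bounds)} exchanges; "
          f"fold changes applied to {sorted(fold_changes.fold_changes)}")
    print(f"Non-survivor model relaxed: {sorted(relaxed) or 'nothing'}")

    summaries = {}
    for name, m in [("survivor", survivor), ("non_survivor", non_survivor)]:
        s = eg.sample_fluxes(m, n_samples=300, seed=seed, thinning=20)
        summaries[name] = eg.summarize_exchanges(s, biomarkers)
    table = eg.biomarker_direction_table(summaries, biomarkers, reference="survivor")
    table.to_csv(RESULTS / "biomarker_directions_patients.tsv", sep="\t")
    print("Patient biomarker directions (reference: survivor):")
    print(table.to_string())

    bounds_out = {
        rid: {"survivor": survivor_bounds[rid], "non_survivor": ns_bounds[rid]}
        for rid in survivor_bounds
    }
    (RESULTS / "patient_bounds.json").write_text(json.dumps(bounds_out, indent=2))


if __name__ == "__main__":
    main()
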