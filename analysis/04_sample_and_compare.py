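#!/usr/bin/env python
"""Sample the context models and compare their flux spaces.

Random sampling of both constrained models, per-reaction fold changes with
sampling-based t-tests, hierarchical clustering (1 - Spearman) of the changed
reactions, the per-super-subsystem cluster composition, and the culture-model
biomarker direction table.  Tables land in results/.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import endogem as eg  # noqa: E402

RESULTS = ROOT / "results"
SEED = 1
N_SAMPLES = 500


def main(seed: int = SEED) -> None:
    models = {name: eg.load_model(RESULTS / f"model_{name}.json") for name in ("control", "treated")}
    samples = {
        name: eg.sample_fluxes(m, n_samples=N_SAMPLES, seed=seed, thinning=20)
        for name, m in models.items()
    }

    comparison = eg.compare_models(samples["control"], samples["treated"])
    comparison.table.to_csv(RESULTS / "flux_comparison.tsv", sep="\t")
    selected = sorted(comparison.selected)
    n_sig = int(comparison.table["significant"].sum())
    print(f"{len(selected)} reactions changed >= 2-fold or flipped sign; "
          f"{n_sig} significant after Bonferroni ({comparison.note})")
    flips = comparison.table.index[comparison.table["sign_flip"]].tolist()
    print(f"Sign flips: {flips}")

    if len(selected) >= 2:
        means = pd.DataFrame(
            {
                "control": samples["control"].points.mean(axis=0),
                "treated": samples["treated"].points.mean(axis=0),
            },
            index=samples["control"].reaction_ids,
        ).loc[selected]
        ss_map = {
            rid: models["control"].reaction(rid).super_subsystem for rid in selected
        }
        report = eg.cluster_changed_reactions(means, n_clusters=2, super_subsystems=ss_map)
        pd.Series(report.labels, name="cluster").rename_axis("reaction_id").to_csv(
            RESULTS / "flux_clusters.tsv", sep="\t"
        )
        report.subsystem_table.to_csv(RESULTS / "cluster_subsystems.tsv", sep="\t", index=False)
        shares = report.subsystem_table.sort_values("share", ascending=False)
        top = shares.iloc[0]
        print(f"Most altered super subsystem: {top['super_subsystem']} "
              f"(share {top['share']:.2f} of its reactions in cluster {top['cluster']})")

    summaries = {
        name: eg.summarize_exchanges(s, eg.BIOMARKER_EXCHANGES) for name, s in samples.items()
    }
    table = eg.biomarker_direction_table(summaries, eg.BIOMARKER_EXCHANGES, reference="control")
    table.to_csv(RESULTS / "biomarker_directions_culture.tsv", sep="\t")
    print("Culture biomarker directions:")
    print(table.to_string())


if __name__ == "__main__":
    main()
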