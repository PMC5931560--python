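#!/usr/bin/env python
"""Generate the synthetic omics inputs with known planted truth.

Emulates the study's data layers for the toy network: two-condition expression
profiles with planted up/down regulation, exchange-rate measurements around
condition-specific flux points (the treated condition flips methoxy-tryptophan
from secretion to uptake), and a plasma fold-change table for the patient
models.  Everything is written to results/ together with the ground truth.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import endogem as eg  # noqa: E402
from endogem.model_io import write_expression_table  # noqa: E402

RESULTS = ROOT / "results"
SEED = 1

PINS_CONTROL = {"EX_mtrp": 0.4, "EX_no": 0.3, "EX_kyn": 0.2, "EX_s1p": 0.1,
                "EX_pgd2": -0.2, "EX_gaba": -0.1}
PINS_TREATED = {**PINS_CONTROL, "EX_mtrp": -0.4}
PATIENT_FC = {"EX_no": 2.0, "EX_kyn": 5.0, "EX_s1p": 0.2, "EX_mtrp": 3.0}


def pinned_point(model, pins):
    work = model.copy()
    for rid, v in pins.items():
        work.reaction(rid).lower_bound = v
        work.reaction(rid).upper_bound = v
    sol = eg.fba(work)
    assert sol.status == "optimal"
    return sol.fluxes


def main(seed: int = SEED) -> None:
    RESULTS.mkdir(exist_ok=True)
    model = eg.load_model(RESULTS / "toy_model.json")

    profiles, reg_truth = eg.simulate_expression(
        model, (0.2, 0.2), effect_size=2.0, seed=seed, absent_rate=0.0
    )
    for name, prof in profiles.items():
        write_expression_table(prof, RESULTS / f"expression_{name}.tsv")
    print(f"Planted {len(reg_truth.up_genes)} up- and {len(reg_truth.down_genes)} "
          f"down-regulated genes at effect size 2.0")

    truth = {
        "seed": seed,
        "up_genes": sorted(reg_truth.up_genes),
        "down_genes": sorted(reg_truth.down_genes),
        "pins": {"control": PINS_CONTROL, "treated": PINS_TREATED},
    }
    measurements = {}
    for offset, (name, pins) in enumerate([("control", PINS_CONTROL), ("treated", PINS_TREATED)]):
        point = pinned_point(model, pins)
        ms, ms_truth = eg.simulate_exchange_measurements(
            model, point, cv=0.02, replicates=3, seed=seed + offset, condition=name
        )
        measurements[name] = ms.rates
        truth[f"true_exchange_means_{name}"] = ms_truth.exchange_means[name]
        print(f"{name}: measured {len(ms.rates)} exchange rates "
              f"(EX_mtrp true rate {pins['EX_mtrp']:+.1f})")
    (RESULTS / "exchange_measurements.json").write_text(json.dumps(measurements, indent=2))

    fc, fc_truth = eg.simulate_patient_fold_changes(PATIENT_FC, seed=seed)
    (RESULTS / "patient_fold_changes.json").write_text(json.dumps(fc.fold_changes, indent=2))
    truth["patient_fold_changes"] = fc_truth.fold_changes
    (RESULTS / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    print(f"Patient plasma fold changes planted on {sorted(fc.fold_changes)}")


if __name__ == "__main__":
    main()
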