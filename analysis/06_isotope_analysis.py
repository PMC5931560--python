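#!/usr/bin/env python
"""13C lactate labelling: theoretical bases, correction, mixture estimation.

Prints the theoretical lactate mass-isotopomer distributions for a purely
glycolytic and a purely oxidative-PPP system under 1,2-13C glucose, runs the
natural-abundance correction round trip on a planted 70/30 mixture, and
estimates the glycolysis fraction from noise-free and noisy data.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import endogem as eg  # noqa: E402

RESULTS = ROOT / "results"
SEED = 1


def main(seed: int = SEED) -> None:
    RESULTS.mkdir(exist_ok=True)
    g = eg.theoretical_lactate_distribution("glycolysis")
    p = eg.theoretical_lactate_distribution("oxppp")
    pd.DataFrame(
        {"glycolysis": g.fractions, "oxppp": p.fractions},
        index=["M0", "M1", "M2", "M3"],
    ).to_csv(RESULTS / "theoretical_lactate_distributions.tsv", sep="\t")
    print("Theoretical lactate distributions (1,2-13C glucose):")
    print(f"  glycolysis M0..M3: {g.fractions}")
    print(f"  oxidative PPP M0..M3: {p.fractions}")

    truth = 0.70 * g.fractions + 0.30 * p.fractions
    raw = eg.add_natural_abundance(truth)  # what the spectrometer would see
    corrected = eg.correct_natural_abundance(raw, 3)
    est = eg.estimate_pathway_fractions(corrected)
    print(f"Planted 70/30 mixture: corrected round-trip error "
          f"{np.abs(corrected.fractions - truth).max():.2e}, "
          f"estimated glycolysis fraction {est.f_glycolysis:.4f}")

    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(100):
        noisy = truth * (1.0 + rng.normal(0.0, 0.01, size=4))
        noisy = np.clip(noisy, 0, None)
        noisy /= noisy.sum()
        errors.append(abs(eg.estimate_pathway_fractions(noisy).f_glycolysis - 0.70))
    print(f"Under 1% relative noise (100 draws): mean |error| {np.mean(errors):.4f}, "
          f"max {max(errors):.4f}")

    (RESULTS / "isotope_estimates.json").write_text(json.dumps(
        {
            "glycolysis_basis": g.fractions.tolist(),
            "oxppp_basis": p.fractions.tolist(),
            "planted_fraction": 0.70,
            "estimated_fraction_noise_free": est.f_glycolysis,
            "mean_abs_error_1pct_noise": float(np.mean(errors)),
        },
        indent=2,
    ))


if __name__ == "__main__":
    main()
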