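"""13C isotopologue processing for the glycolysis / pentose-phosphate split.

Cells fed 1,2-13C glucose secrete lactate whose mass-isotopomer distribution
(M0..M3) reports on the route glucose took: glycolysis cleaves
fructose-1,6-bisphosphate so the C1+C2 labels stay together on one triose
(M2 lactate), while the oxidative PPP decarboxylates C1 so single-label (M1)
lactate appears.  This module provides

* natural-abundance correction of measured isotopologue intensities (binomial
  convolution matrix, solved with non-negative least squares),
* theoretical lactate label distributions for a purely glycolytic and a purely
  (single-pass) oxidative-PPP system, generated by atom-mapped propagation,
* a constrained least-squares estimator of the glycolysis fraction from a
  corrected lactate distribution, and
* the metabolomics normalisation chain (per-batch root-sum-of-squares,
  constant-sum, log transform, unit-variance autoscaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import comb

NATURAL_13C_ABUNDANCE = 0.0107

__all__ = [
    "IsotopologueDistribution",
    "PathwayFractionEstimate",
    "add_natural_abundance",
    "correct_natural_abundance",
    "theoretical_lactate_distribution",
    "estimate_pathway_fractions",
    "normalize_metabolomics",
    "NATURAL_13C_ABUNDANCE",
]


@dataclass
class IsotopologueDistribution:
    """Mass-isotopomer fractions M0..Mn of one metabolite (n = carbon count)."""

    metabolite_id: str
    fractions: np.ndarray
    source: str = "raw"  # raw | corrected | theoretical

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if (self.fractions < -1e-12).any():
            raise ValueError(f"{self.metabolite_id}: negative isotopologue fractions")
        total = self.fractions.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(
                f"{self.metabolite_id}: fractions sum to {total}, expected 1"
            )

    @property
    def n_carbons(self) -> int:
        return len(self.fractions) - 1


@dataclass
class PathwayFractionEstimate:
    f_glycolysis: float
    f_ppp: float
    residual: float

    def __post_init__(self) -> None:
        if not np.isclose(self.f_glycolysis + self.f_ppp, 1.0):
            raise ValueError("pathway fractions must sum to 1")


def _natural_abundance_matrix(n_carbons: int, p: float) -> np.ndarray:
    """C with raw = C @ true; C[i, j] = P(i-j of the n-j light carbons are 13C)."""
    n = n_carbons
    C = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        for i in range(j, n + 1):
            k = i - j
            C[i, j] = comb(n - j, k, exact=True) * p**k * (1 - p) ** (n - j - k)
    return C


def add_natural_abundance(
    fractions: np.ndarray, n_carbons: int | None = None, p: float = NATURAL_13C_ABUNDANCE
) -> np.ndarray:
    """Forward-convolve a tracer-only distribution with natural 13C abundance."""
    fractions = np.asarray(fractions, dtype=float)
    n = n_carbons if n_carbons is not None else len(fractions) - 1
    return _natural_abundance_matrix(n, p) @ fractions


def correct_natural_abundance(
    raw: IsotopologueDistribution | np.ndarray,
    n_carbons: int | None = None,
    abundance_13c: float = NATURAL_13C_ABUNDANCE,
    metabolite_id: str = "",
) -> IsotopologueDistribution:
    """Remove natural 13C abundance from a measured isotopologue distribution.

    Solves the triangular binomial convolution system with a non-negativity
    constraint and renormalises; with abundance 0 the transform is the
    identity, and correct(convolve(x)) = x for any simplex vector x.
    """
    if isinstance(raw, IsotopologueDistribution):
        vec = raw.fractions
        n = raw.n_carbons
        mid = metabolite_id or raw.metabolite_id
    else:
        vec = np.asarray(raw, dtype=float)
        n = n_carbons if n_carbons is not None else len(vec) - 1
        mid = metabolite_id or "metabolite"
    if (vec < 0).any():
        raise ValueError("raw isotopologue intensities must be non-negative")
    if len(vec) != n + 1:
        raise ValueError(f"expected {n + 1} isotopologue fractions, got {len(vec)}")
    C = _natural_abundance_matrix(n, abundance_13c)
    corrected, _ = nnls(C, vec)
    total = corrected.sum()
    if total <= 0:
        raise ValueError("correction produced an all-zero distribution")
    return IsotopologueDistribution(mid, corrected / total, source="corrected")


# ---------------------------------------------------------------------------
# Theoretical lactate labelling from 1,2-13C glucose
# ---------------------------------------------------------------------------
#
# Atom maps (glucose carbons numbered 1..6; tracer labels C1 and C2):
#
# Glycolysis: F1,6BP cleaves into DHAP (C1-C3, order reversed on the way to
# GAP) and GAP (C4-C6); each glucose yields one M2 lactate (labels C1+C2) and
# one M0 lactate.
#
# Single-pass oxidative PPP (no F6P re-entry): 3 glucose -> 3 CO2 (the
# labelled C1s) + 3 pentose-P each labelled at its C1 (former glucose C2).
# Transketolase/transaldolase recombination (2 Xu5P + 1 R5P -> 2 F6P + 1 GAP)
# places those labels on F6P C1 and C3; the resulting five trioses enter lower
# glycolysis.  Per 3 glucose: one M2, one M1 and three M0 lactate.


def _triose_labels_from_hexose(hexose: tuple[int, ...]) -> list[int]:
    """Label counts of the two pyruvate/lactate molecules from one hexose."""
    dhap_half = hexose[0:3]  # C1-C3, reversed into GAP; count is order-free
    gap_half = hexose[3:6]
    return [sum(dhap_half), sum(gap_half)]


def _glycolysis_lactate_labels(glucose: tuple[int, ...]) -> list[int]:
    return _triose_labels_from_hexose(glucose)


def _oxppp_lactate_labels(glucose: tuple[int, ...]) -> list[int]:
    """Single-pass oxPPP fate of three identical glucose molecules."""
    # Oxidative branch: lose C1, keep C2-C6 as pentose-P (pentose C1 = glc C2).
    pentose = glucose[1:6]
    r5p = pentose
    xu5p_1 = pentose
    xu5p_2 = pentose
    # TK1: Xu5P(C1,C2) + R5P -> S7P(C1,C2 from Xu; C3-C7 from R5P) + GAP(Xu C3-C5)
    s7p = xu5p_1[0:2] + r5p
    gap_1 = xu5p_1[2:5]
    # TA: S7P(C1-C3) + GAP -> F6P(C1-C3 from S7P; C4-C6 from GAP) + E4P(S7P C4-C7)
    f6p_1 = s7p[0:3] + gap_1
    e4p = s7p[3:7]
    # TK2: Xu5P(C1,C2) + E4P -> F6P(C1,C2 from Xu; C3-C6 from E4P) + GAP(Xu C3-C5)
    f6p_2 = xu5p_2[0:2] + e4p
    gap_2 = xu5p_2[2:5]
    labels = []
    labels += _triose_labels_from_hexose(tuple(f6p_1))
    labels += _triose_labels_from_hexose(tuple(f6p_2))
    labels.append(sum(gap_2))
    return labels


def theoretical_lactate_distribution(
    pathway: str, tracer: tuple[int, ...] = (1, 1, 0, 0, 0, 0)
) -> IsotopologueDistribution:
    """Lactate M0..M3 for a purely glycolytic or purely oxidative-PPP system.

    The tracer is 1,2-13C glucose by default; an unlabelled tracer returns
    M0 = 1 for either pathway.
    """
    if len(tracer) != 6:
        raise ValueError("tracer must give the label state of 6 glucose carbons")
    if pathway == "glycolysis":
        labels = _glycolysis_lactate_labels(tuple(tracer))
    elif pathway == "oxppp":
        labels = _oxppp_lactate_labels(tuple(tracer))
    else:
        raise ValueError(f"unknown pathway {pathway!r}; expected 'glycolysis' or 'oxppp'")
    fractions = np.zeros(4)
    for k in labels:
        fractions[k] += 1
    fractions /= fractions.sum()
    return IsotopologueDistribution("lactate", fractions, source="theoretical")


def estimate_pathway_fractions(
    corrected: IsotopologueDistribution | np.ndarray,
) -> PathwayFractionEstimate:
    """Glycolysis/PPP mixture fractions from a corrected lactate distribution.

    Least-squares projection of the observed vector onto the segment between
    the two theoretical basis distributions, constrained to the simplex
    (f_gly + f_ppp = 1, both non-negative); the Euclidean residual is reported.
    """
    x = (
        corrected.fractions
        if isinstance(corrected, IsotopologueDistribution)
        else np.asarray(corrected, dtype=float)
    )
    g = theoretical_lactate_distribution("glycolysis").fractions
    p = theoretical_lactate_distribution("oxppp").fractions
    d = g - p
    denom = float(d @ d)
    if denom < 1e-12:
        raise ValueError("degenerate basis: pathway distributions coincide")
    f = float(np.clip((x - p) @ d / denom, 0.0, 1.0))
    residual = float(np.linalg.norm(f * g + (1 - f) * p - x))
    return PathwayFractionEstimate(f, 1.0 - f, residual)


# ---------------------------------------------------------------------------
# Metabolomics normalisation chain
# ---------------------------------------------------------------------------


def normalize_metabolomics(batches: dict[str, pd.DataFrame] | list[pd.DataFrame]) -> pd.DataFrame:
    """Normalise raw intensity batches (samples x metabolites).

    Pipeline: (1) per batch, divide each variable by its root-sum-of-squares;
    (2) per sample, constant-sum normalisation; (3) natural log; (4) per
    variable, mean-centre and scale to unit variance.  Inputs must be
    non-negative with missing values already replaced by per-variable minimum
    positives; an all-zero variable in any batch is an error.
    """
    if isinstance(batches, dict):
        items = list(batches.items())
    else:
        items = [(f"batch{i}", b) for i, b in enumerate(batches)]
    scaled = []
    for name, df in items:
        df = df.astype(float)
        if (df.values < 0).any():
            raise ValueError(f"batch {name!r}: negative intensities")
        rss = np.sqrt((df**2).sum(axis=0))
        zero = rss[rss == 0].index.tolist()
        if zero:
            raise ValueError(f"batch {name!r}: all-zero variables {zero}")
        scaled.append(df / rss)
    mat = pd.concat(scaled, axis=0)
    row_sums = mat.sum(axis=1)
    if (row_sums <= 0).any():
        raise ValueError("constant-sum normalisation: sample with non-positive total")
    mat = mat.div(row_sums, axis=0)
    if (mat.values <= 0).any():
        raise ValueError("log transform requires strictly positive values; replace missing values first")
    mat = np.log(mat)
    centred = mat - mat.mean(axis=0)
    std = mat.std(axis=0, ddof=1)
    if (std == 0).any():
        zero = std[std == 0].index.tolist()
        raise ValueError(f"unit-variance scaling: constant variables {zero}")
    return centred / std
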