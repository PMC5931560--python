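"""Cross-model comparison of sampled flux spaces.

Given flux samples of two or more context-specific models, this module
computes per-reaction fold changes of sampled means (with a pseudocount for
near-zero fluxes and explicit handling of sign flips), two-sample t-tests with
Bonferroni correction, average-linkage hierarchical clustering of changed
reactions under the 1 - Spearman correlation distance, per-super-subsystem
cluster composition tables, and biomarker secretion/uptake direction tables.

Statistical caveat carried in all outputs: flux samples are pseudo-replicates
drawn from a model's solution space, not biological replicates; p-values are
"sampling-based significance" of separation between flux distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .sampling import ExchangeSummary, FluxSample

FOLD_PSEUDOCOUNT = 1e-9
DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_ALPHA = 0.05

__all__ = [
    "FluxComparison",
    "ClusterReport",
    "compare_models",
    "cluster_changed_reactions",
    "biomarker_direction_table",
]


@dataclass
class FluxComparison:
    """Per-reaction comparison table between two sampled models.

    ``table`` columns: mean_a, mean_b, fold_change (>= 1, max/min oriented),
    direction ('b>a' or 'a>b' by |mean|), sign_flip, p_value, p_bonferroni,
    significant, selected.  The note field records the pseudo-replicate caveat.
    """

    table: pd.DataFrame
    fold_threshold: float
    alpha: float
    note: str = "sampling-based significance (flux samples are pseudo-replicates)"

    @property
    def selected(self) -> set[str]:
        return set(self.table.index[self.table["selected"]])


def compare_models(
    sample_a: FluxSample,
    sample_b: FluxSample,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = FOLD_PSEUDOCOUNT,
) -> FluxComparison:
    """Fold changes, sign flips and Bonferroni-corrected t-tests per reaction.

    Fold change is (max|mean| + d) / (min|mean| + d) with pseudocount d; a
    reaction is *selected* when the fold change reaches the threshold or the
    means flip sign.  The equal-variance two-tailed t-test runs on the sampled
    flux columns; Bonferroni corrects over the reactions tested.
    """
    if sample_a.reaction_ids != sample_b.reaction_ids:
        raise ValueError("samples cover different reaction sets or orderings")
    rids = sample_a.reaction_ids
    mean_a = sample_a.points.mean(axis=0)
    mean_b = sample_b.points.mean(axis=0)
    abs_a, abs_b = np.abs(mean_a), np.abs(mean_b)
    fold = (np.maximum(abs_a, abs_b) + pseudocount) / (np.minimum(abs_a, abs_b) + pseudocount)
    sign_flip = (mean_a * mean_b) < -(pseudocount**2)
    direction = np.where(abs_b >= abs_a, "b>a", "a>b")
    tstat, pval = stats.ttest_ind(sample_a.points, sample_b.points, axis=0, equal_var=True)
    pval = np.where(np.isnan(pval), 1.0, pval)  # constant identical columns
    n_tests = len(rids)
    p_bonf = np.minimum(pval * n_tests, 1.0)
    # the pseudocount shifts an exact k-fold pair infinitesimally below k
    selected = (fold >= fold_threshold * (1.0 - 1e-9)) | sign_flip
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold,
            "direction": direction,
            "sign_flip": sign_flip,
            "t_statistic": tstat,
            "p_value": pval,
            "p_bonferroni": p_bonf,
            "significant": p_bonf <= alpha,
            "selected": selected,
        },
        index=pd.Index(rids, name="reaction_id"),
    )
    return FluxComparison(table, fold_threshold, alpha)


@dataclass
class ClusterReport:
    labels: dict[str, int]
    linkage_description: str
    distance: str
    subsystem_table: pd.DataFrame  # columns: cluster, super_subsystem, count, share


def cluster_changed_reactions(
    flux_means: pd.DataFrame,
    n_clusters: int | None = None,
    cut_height: float | None = None,
    super_subsystems: dict[str, str] | None = None,
) -> ClusterReport:
    """Average-linkage clustering of reaction flux profiles across models.

    Rows of ``flux_means`` are reactions passing the fold threshold, columns
    are models; the distance between row profiles is 1 - Spearman rank
    correlation.  Cluster labels are deterministic: clusters are renumbered by
    first appearance in lexicographic reaction-id order.  The subsystem table
    reports, per (cluster, super subsystem), the reaction count and the share
    normalised to the total reactions of that super subsystem.
    """
    if flux_means.shape[0] < 2:
        raise ValueError("clustering needs at least 2 reactions")
    if (n_clusters is None) == (cut_height is None):
        raise ValueError("give exactly one of n_clusters or cut_height")
    order = np.argsort(flux_means.index)
    df = flux_means.iloc[order]
    rho, _ = stats.spearmanr(df.values, axis=1)
    rho = np.atleast_2d(rho)
    if rho.shape != (df.shape[0], df.shape[0]):  # spearmanr collapses for 2 rows
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
    dist = 1.0 - rho
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    if n_clusters is not None:
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        raw = fcluster(Z, t=cut_height, criterion="distance")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for rid, lab in zip(df.index, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[rid] = relabel[lab]

    ss_map = super_subsystems or {}
    totals: dict[str, int] = {}
    for ss in ss_map.values():
        totals[ss] = totals.get(ss, 0) + 1
    rows = []
    counted: dict[tuple[int, str], int] = {}
    for rid, lab in labels.items():
        ss = ss_map.get(rid, "unassigned")
        counted[(lab, ss)] = counted.get((lab, ss), 0) + 1
    for (lab, ss), count in sorted(counted.items()):
        total = totals.get(ss, count)
        rows.append(
            {
                "cluster": lab,
                "super_subsystem": ss,
                "count": count,
                "share": count / total if total else np.nan,
            }
        )
    table = pd.DataFrame(rows, columns=["cluster", "super_subsystem", "count", "share"])
    return ClusterReport(
        labels,
        "average linkage on row profiles",
        "1 - Spearman rank correlation",
        table,
    )


def biomarker_direction_table(
    summaries: dict[str, ExchangeSummary],
    biomarker_exchange_ids: list[str],
    reference: str | None = None,
    rel_tolerance: float = 1e-9,
) -> pd.DataFrame:
    """Biomarker direction (secretion/uptake) and level vs a reference model.

    One row per biomarker exchange; per model a ``<model>_direction`` column
    and, for non-reference models, a ``<model>_level`` column with increase /
    decrease / unchanged relative to the reference model's sampled mean.
    """
    if not summaries:
        raise ValueError("no model summaries given")
    models = list(summaries)
    ref = reference or models[0]
    if ref not in summaries:
        raise KeyError(f"reference model {ref!r} not among summaries")
    for name, summ in summaries.items():
        missing = set(biomarker_exchange_ids) - set(summ.stats.index)
        if missing:
            raise KeyError(f"model {name!r} summary misses biomarkers {sorted(missing)}")
    rows = []
    for rid in biomarker_exchange_ids:
        row: dict[str, object] = {"biomarker_exchange": rid}
        ref_mean = summaries[ref].mean(rid)
        for name in models:
            summ = summaries[name]
            row[f"{name}_direction"] = summ.direction(rid)
            if name == ref:
                continue
            delta = summ.mean(rid) - ref_mean
            if delta > rel_tolerance:
                row[f"{name}_level"] = "increase"
            elif delta < -rel_tolerance:
                row[f"{name}_level"] = "decrease"
            else:
                row[f"{name}_level"] = "unchanged"
        rows.append(row)
    return pd.DataFrame(rows).set_index("biomarker_exchange")
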