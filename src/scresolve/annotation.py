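"""Cluster annotation from marker catalogs and manual cell-set comparisons.

Annotation assigns each cluster to the catalogued cell type whose marker
genes have the best (smallest) aggregate expression rank within the
cluster.  This is a labelling convenience, not a classifier; reference- or
model-based cell-type assignment is deliberately out of scope.

Cell-set comparison re-uses the full DE machinery on a user-defined
three-group labelling (set A, set B, remaining cells), so any two selections
of cells can be contrasted with the same statistics as cluster pairs, and
the result behaves like an extra pseudo cluster solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_stats import (
    ClusterGeneStats,
    ClusterSolution,
    NormalizedExpressionMatrix,
    compute_cluster_gene_stats,
)
from .de_testing import (
    DEParams,
    DEResultPairwise,
    DEResultVsRest,
    calc_de_combn,
    calc_de_vs_rest,
)

__all__ = [
    "MarkerCatalog",
    "CellSetComparison",
    "rank_genes_in_cluster",
    "annotate_clusters",
    "compare_cell_sets",
    "volcano_table",
    "ma_table",
]


@dataclass
class MarkerCatalog:
    """Mapping of cell-type name to its canonical marker genes."""

    types: dict[str, list[str]]

    def __post_init__(self):
        if not self.types:
            raise ValueError("marker catalog is empty")
        for name, genes in self.types.items():
            if not genes:
                raise ValueError(f"cell type {name!r} has no marker genes")
            self.types[name] = [str(g) for g in genes]


@dataclass
class CellSetComparison:
    """DE results for two user-selected, disjoint cell sets.

    Represented as a pseudo cluster solution with groups ``label_a``,
    ``label_b`` and (when non-empty) ``rest``, so the comparison can be
    archived and explored exactly like a clustering solution.
    """

    comparison_id: str
    set_a: pd.Index
    set_b: pd.Index
    label_a: str
    label_b: str
    solution: ClusterSolution
    stats: ClusterGeneStats
    de_combn: DEResultPairwise
    de_vs_rest: DEResultVsRest | None
    params: DEParams

    def pair_table(self) -> pd.DataFrame:
        """The A-versus-B pairwise table, oriented toward set A."""
        table, sign = self.de_combn.table_for(self.label_a, self.label_b)
        if sign == 1:
            return table
        flipped = table.copy()
        flipped["logGER"] = -flipped["logGER"]
        flipped["dDR"] = -flipped["dDR"]
        return flipped


def rank_genes_in_cluster(stats: ClusterGeneStats, cluster: str) -> pd.Series:
    """Rank genes within a cluster, 1 = highest expression.

    Genes are ordered by descending MGE, ties broken by descending DR, then
    by gene name; the result is deterministic and independent of cell order.
    """
    if cluster not in stats.frames:
        raise KeyError(f"unknown cluster {cluster!r}")
    f = stats.frames[cluster]
    order = f.assign(_gene=f.index).sort_values(
        ["MGE", "DR", "_gene"], ascending=[False, False, True], kind="mergesort"
    )
    ranks = pd.Series(
        np.arange(1, len(order) + 1), index=order.index, name="rank"
    )
    return ranks.reindex(f.index)


def annotate_clusters(
    stats: ClusterGeneStats, catalog: MarkerCatalog, metric: str = "MGE"
) -> dict[str, str]:
    """Label each cluster with the cell type of top aggregate marker rank.

    For each cluster, a type's aggregate rank is the arithmetic mean rank of
    its catalog genes that are present in the data (absent genes are
    ignored, not penalized); the type with the smallest aggregate wins, ties
    going to the first type in name order.  ``metric`` selects the statistic
    ranked (MGE by default; MDGE or DR alternatively).
    """
    if metric not in ("MGE", "MDGE", "DR"):
        raise ValueError(f"metric must be MGE, MDGE or DR: {metric!r}")
    genes = stats.gene_ids
    present = {
        t: [g for g in gs if g in genes] for t, gs in catalog.types.items()
    }
    usable = {t: gs for t, gs in present.items() if gs}
    if not usable:
        raise ValueError("no catalog gene is present in the data for any type")
    labels: dict[str, str] = {}
    for cluster in stats.clusters:
        if metric == "MGE":
            ranks = rank_genes_in_cluster(stats, cluster)
        else:
            f = stats.frames[cluster]
            order = f.assign(_gene=f.index).sort_values(
                [metric, "_gene"], ascending=[False, True], kind="mergesort"
            )
            ranks = pd.Series(
                np.arange(1, len(order) + 1), index=order.index
            ).reindex(f.index)
        aggregate = {
            t: float(ranks.loc[gs].mean()) for t, gs in sorted(usable.items())
        }
        labels[cluster] = min(sorted(aggregate), key=aggregate.get)
    return labels


def compare_cell_sets(
    m: NormalizedExpressionMatrix,
    set_a,
    set_b,
    params: DEParams | None = None,
    comparison_id: str = "comparison",
    label_a: str = "setA",
    label_b: str = "setB",
) -> CellSetComparison:
    """Differential expression between two disjoint cell selections.

    Builds a pseudo solution labelling cells ``label_a`` / ``label_b`` /
    ``rest`` and runs the pairwise and vs-rest machinery on it.  When the
    two sets cover all cells the vs-rest comparison is skipped with a
    warning (there is no "rest" to compare against).
    """
    params = params or DEParams()
    a = pd.Index(pd.unique(np.asarray(list(set_a), dtype=object).astype(str)))
    b = pd.Index(pd.unique(np.asarray(list(set_b), dtype=object).astype(str)))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both cell sets must be non-empty")
    overlap = a.intersection(b)
    if len(overlap):
        raise ValueError(f"cell sets overlap: {overlap.tolist()[:5]}")
    unknown = a.union(b).difference(m.cell_ids)
    if len(unknown):
        raise ValueError(f"unknown cell ids: {unknown.tolist()[:5]}")
    labels = pd.Series("rest", index=m.cell_ids, dtype=object)
    labels.loc[a] = label_a
    labels.loc[b] = label_b
    has_rest = (labels == "rest").any()
    if not has_rest:
        labels = labels[labels != "rest"]
    solution = ClusterSolution(solution_id=comparison_id, labels=labels)
    if has_rest:
        stats = compute_cluster_gene_stats(m, solution)
        vs_rest = calc_de_vs_rest(m, solution, stats, params)
    else:
        warnings.warn(
            "cell sets cover all cells; vs-rest comparison skipped",
            stacklevel=2,
        )
        stats = compute_cluster_gene_stats(m, solution)
        vs_rest = None
    combn = calc_de_combn(m, solution, stats, params)
    return CellSetComparison(
        comparison_id=comparison_id,
        set_a=a,
        set_b=b,
        label_a=label_a,
        label_b=label_b,
        solution=solution,
        stats=stats,
        de_combn=combn,
        de_vs_rest=vs_rest,
        params=params,
    )


def volcano_table(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (logGER, -log10 FDR) for tested genes.

    FDR values of exactly 0 are clamped to half the smallest nonzero FDR in
    the table (or the smallest positive float when every FDR is 0) so the
    log transform stays finite.
    """
    tested = pair_table[pair_table["tested"].astype(bool)]
    fdr = tested["FDR"].to_numpy(dtype=float).copy()
    nonzero = fdr[fdr > 0]
    clamp = nonzero.min() / 2 if nonzero.size else np.finfo(float).tiny
    fdr[fdr == 0] = clamp
    return pd.DataFrame(
        {"logGER": tested["logGER"], "neg_log10_FDR": -np.log10(fdr)},
        index=tested.index,
    )


def ma_table(
    statsA: pd.DataFrame, statsB: pd.DataFrame, metric: str = "DR"
) -> pd.DataFrame:
    """Per-gene difference and average of a cluster statistic for two groups.

    ``metric`` is one of MGE, MDGE, DR; difference = A - B, average =
    (A + B) / 2.  Feeds MA-style difference-vs-mean displays.
    """
    for f in (statsA, statsB):
        if metric not in f.columns:
            raise ValueError(f"metric {metric!r} not available in stats frame")
    a = statsA[metric]
    b = statsB[metric].reindex(a.index)
    return pd.DataFrame(
        {"difference": a - b, "average": (a + b) / 2}, index=a.index
    )
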