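"""Cluster-granularity assessment across clustering resolutions.

A clustering solution is judged by whether its clusters are separable by
gene expression:

* **marker genes** — genes significantly positively differentially
  expressed in a cluster against *every* other cluster in pairwise tests;
* **neighbour DE** — genes significantly positively differentially
  expressed between a cluster and its *nearest neighbour*, the cluster it is
  hardest to distinguish from (fewest significant genes, either direction,
  in the pairwise tests).

A solution "passes" when every cluster has at least one positively DE gene
against its nearest neighbour; losing that separability indicates
over-clustering.  :func:`sweep_resolutions` processes solutions in order of
increasing cluster count and can stop once separability is lost.

Silhouette widths on the reduced-dimension embedding used for clustering
(Euclidean distance, axes taken as-is with no reweighting) complement the
DE-based metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

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
    "SolutionAssessment",
    "SilhouetteResult",
    "AssessmentRow",
    "AssessmentSummary",
    "count_significant_genes",
    "find_nearest_neighbors",
    "de_neighb",
    "de_marker",
    "silhouette_widths",
    "summarize_resolution",
    "sweep_resolutions",
]


@dataclass
class SilhouetteResult:
    """Per-cell silhouette widths plus per-cluster and overall means."""

    widths: pd.Series
    cluster_means: pd.Series
    overall_mean: float


@dataclass
class SolutionAssessment:
    """Precomputed assessment results for one clustering solution."""

    solution_id: str
    solution: ClusterSolution
    stats: ClusterGeneStats
    de_vs_rest: DEResultVsRest | None
    de_combn: DEResultPairwise | None
    silhouette: SilhouetteResult | None
    params: DEParams

    @property
    def n_clusters(self) -> int:
        return self.solution.n_clusters


def count_significant_genes(
    pair_table: pd.DataFrame,
    fdr_threshold: float,
    direction: str = "both",
    sign: int = 1,
) -> int:
    """Count genes significant at ``FDR < fdr_threshold`` in a pair table.

    ``direction='positive'`` additionally requires the effect to point
    toward the query cluster: ``sign * logGER > 0``, where ``sign`` is the
    query cluster's orientation in the table (+1 first-named, -1 second).
    """
    if direction not in ("both", "positive"):
        raise ValueError(f"direction must be 'both' or 'positive': {direction!r}")
    mask = pair_table["FDR"] < fdr_threshold  # NaN (untested) compares False
    if direction == "positive":
        mask &= sign * pair_table["logGER"] > 0
    return int(mask.sum())


def find_nearest_neighbors(
    combn: DEResultPairwise, params: DEParams | None = None
) -> dict[str, str]:
    """Nearest neighbour of each cluster: fewest significant DE genes.

    Counts genes significant in either direction; ties are broken by
    cluster-name sort order.
    """
    fdr = (params or combn.params).fdr_threshold
    counts = {
        key: count_significant_genes(t, fdr, direction="both")
        for key, t in combn.tables.items()
    }
    neighbours: dict[str, str] = {}
    for c in combn.clusters:
        others = sorted(o for o in combn.clusters if o != c)
        neighbours[c] = min(
            others, key=lambda o: counts[tuple(sorted((c, o)))]
        )
    return neighbours


def de_neighb(
    assessment: SolutionAssessment, fdr_threshold: float | None = None
) -> dict[str, pd.Index]:
    """Positively DE genes between each cluster and its nearest neighbour."""
    if assessment.de_combn is None:
        raise ValueError("pairwise DE results are required")
    fdr = assessment.params.fdr_threshold if fdr_threshold is None else fdr_threshold
    neighbours = find_nearest_neighbors(assessment.de_combn, assessment.params)
    out: dict[str, pd.Index] = {}
    for c, nb in neighbours.items():
        table, sign = assessment.de_combn.table_for(c, nb)
        mask = (table["FDR"] < fdr) & (sign * table["logGER"] > 0)
        out[c] = table.index[mask.to_numpy()]
    return out


def de_marker(
    assessment: SolutionAssessment, fdr_threshold: float | None = None
) -> dict[str, pd.Index]:
    """Marker genes: positively DE in a cluster against every other cluster."""
    if assessment.de_combn is None:
        raise ValueError("pairwise DE results are required")
    fdr = assessment.params.fdr_threshold if fdr_threshold is None else fdr_threshold
    combn = assessment.de_combn
    out: dict[str, pd.Index] = {}
    for c in combn.clusters:
        keep: pd.Index | None = None
        for other in combn.clusters:
            if other == c:
                continue
            table, sign = combn.table_for(c, other)
            mask = (table["FDR"] < fdr) & (sign * table["logGER"] > 0)
            genes = table.index[mask.to_numpy()]
            keep = genes if keep is None else keep.intersection(genes)
        out[c] = keep if keep is not None else pd.Index([])
    return out


def silhouette_widths(
    embedding: pd.DataFrame, s: ClusterSolution
) -> SilhouetteResult:
    """Silhouette widths on a reduced-dimension embedding.

    For cell i: ``a(i)`` is the mean Euclidean distance to the other cells
    of its cluster, ``b(i)`` the smallest mean distance to the cells of any
    other cluster, and ``s(i) = (b - a) / max(a, b)``.  Cells of singleton
    clusters, and cells where ``max(a, b) = 0`` (coincident points), get
    width 0.  Coordinates are used as-is; axes are never reweighted.
    """
    if set(embedding.index) != set(s.labels.index):
        raise ValueError("embedding rows do not match the clustered cells")
    emb = embedding.reindex(s.labels.index)
    coords = emb.to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("embedding contains non-numeric or non-finite entries")
    labels = s.labels.to_numpy()
    clusters = s.clusters
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(coords, coords)
    members = {c: np.flatnonzero(labels == c) for c in clusters}
    widths = np.zeros(len(labels))
    for c in clusters:
        idx = members[c]
        if len(idx) == 1:
            continue  # singleton convention: width 0
        a = D[np.ix_(idx, idx)].sum(axis=1) / (len(idx) - 1)
        b = np.min(
            [D[np.ix_(idx, members[o])].mean(axis=1) for o in clusters if o != c],
            axis=0,
        )
        denom = np.maximum(a, b)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1), 0.0)
        widths[idx] = w
    per_cell = pd.Series(widths, index=s.labels.index, name="silhouette")
    cluster_means = per_cell.groupby(s.labels).mean().sort_index()
    return SilhouetteResult(
        widths=per_cell,
        cluster_means=cluster_means,
        overall_mean=float(per_cell.mean()),
    )


@dataclass
class AssessmentRow:
    """Granularity summary for one clustering solution."""

    solution_id: str
    n_clusters: int
    neighbours: dict[str, str]
    neighb_counts: dict[str, int]
    marker_counts: dict[str, int]
    mean_silhouette: float
    passed_neighbour_check: bool


@dataclass
class AssessmentSummary:
    """Per-resolution assessment table driving resolution choice."""

    rows: list[AssessmentRow]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "solution_id": [r.solution_id for r in self.rows],
                "n_clusters": [r.n_clusters for r in self.rows],
                "min_neighb_count": [
                    min(r.neighb_counts.values()) if r.neighb_counts else np.nan
                    for r in self.rows
                ],
                "median_neighb_count": [
                    float(np.median(list(r.neighb_counts.values())))
                    if r.neighb_counts
                    else np.nan
                    for r in self.rows
                ],
                "mean_silhouette": [r.mean_silhouette for r in self.rows],
                "passed_neighbour_check": [
                    r.passed_neighbour_check for r in self.rows
                ],
            }
        )

    def per_cluster_json(self) -> dict:
        return {
            r.solution_id: {
                "neighbours": r.neighbours,
                "neighb_counts": r.neighb_counts,
                "marker_counts": r.marker_counts,
            }
            for r in self.rows
        }


def summarize_resolution(assessment: SolutionAssessment) -> AssessmentRow:
    """Condense one solution's results into an assessment row.

    The neighbour check passes iff every cluster has >= 1 positively DE gene
    against its nearest neighbour; for a single-cluster solution there are
    no neighbour pairs and the check passes vacuously.
    """
    if assessment.de_combn is not None:
        neighbours = find_nearest_neighbors(assessment.de_combn, assessment.params)
        neighb_sets = de_neighb(assessment)
        marker_sets = de_marker(assessment)
        neighb_counts = {c: len(neighb_sets[c]) for c in sorted(neighb_sets)}
        marker_counts = {c: len(marker_sets[c]) for c in sorted(marker_sets)}
    else:
        neighbours, neighb_counts, marker_counts = {}, {}, {}
    passed = all(v >= 1 for v in neighb_counts.values())
    sil = assessment.silhouette.overall_mean if assessment.silhouette is not None else float("nan")
    return AssessmentRow(
        solution_id=assessment.solution_id,
        n_clusters=assessment.n_clusters,
        neighbours=neighbours,
        neighb_counts=neighb_counts,
        marker_counts=marker_counts,
        mean_silhouette=sil,
        passed_neighbour_check=passed,
    )


def assess_solution(
    m: NormalizedExpressionMatrix,
    s: ClusterSolution,
    embedding: pd.DataFrame | None = None,
    params: DEParams | None = None,
) -> SolutionAssessment:
    """Compute the full result bundle for a single clustering solution."""
    params = params or DEParams()
    stats = compute_cluster_gene_stats(m, s)
    if s.n_clusters >= 2:
        vs_rest = calc_de_vs_rest(m, s, stats, params)
        combn = calc_de_combn(m, s, stats, params)
        sil = silhouette_widths(embedding, s) if embedding is not None else None
    else:
        vs_rest = combn = sil = None
    return SolutionAssessment(
        solution_id=s.solution_id,
        solution=s,
        stats=stats,
        de_vs_rest=vs_rest,
        de_combn=combn,
        silhouette=sil,
        params=params,
    )


def sweep_resolutions(
    m: NormalizedExpressionMatrix,
    solutions: list[ClusterSolution],
    embedding: pd.DataFrame | None = None,
    params: DEParams | None = None,
    stop_on_loss: bool = False,
) -> tuple[list[SolutionAssessment], AssessmentSummary]:
    """Assess solutions in order of increasing cluster count.

    With ``stop_on_loss``, processing halts after the first solution that
    fails the neighbour check; that solution is retained (flagged in the
    summary) so the failure can be inspected, and later solutions are
    skipped.  Ties in cluster count keep the input order.
    """
    if not solutions:
        raise ValueError("no cluster solutions supplied")
    params = params or DEParams()
    order = sorted(range(len(solutions)), key=lambda i: (solutions[i].n_clusters, i))
    assessments: list[SolutionAssessment] = []
    rows: list[AssessmentRow] = []
    for i in order:
        assessment = assess_solution(m, solutions[i], embedding, params)
        row = summarize_resolution(assessment)
        assessments.append(assessment)
        rows.append(row)
        if stop_on_loss and not row.passed_neighbour_check:
            break
    return assessments, AssessmentSummary(rows=rows)
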