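"""Synthetic cluster-structured scRNA-seq data and pseudocount simulations.

The generator draws sparse counts from a negative-binomial model — the
simplest model that reproduces the strong coupling between expression
magnitude and detection probability seen in droplet-based scRNA-seq — with
per-cluster elevated means for each cluster's exclusive DE genes, then
applies library-size normalization and a log transform, mirroring the
normalization conventions the assessment machinery expects.

Also provided is the single-gene pseudocount simulation: a grid of cluster
mean abundances from 0 to 50 on which the behaviour of the log expression
ratio under different pseudocounts (1, 1e-99, 1/#cells) can be tabulated —
a pseudocount of 1 compresses ratios, 1e-99 sends zero comparisons beyond
magnitude 300, and 1/#cells keeps them within the range of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .cluster_stats import ClusterSolution, NormalizedExpressionMatrix
from .de_testing import calc_logGER

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "simulate_dataset",
    "build_resolution_series",
    "pseudocount_grid",
    "pseudocount_logger_table",
]

#: spread (sigma of the lognormal) of per-gene baseline means
GENE_MEAN_SIGMA = 0.5


@dataclass
class SimulationSpec:
    """Parameters of the cluster-structured negative-binomial simulation.

    ``baseline_mean`` is the average per-gene mean count; simulated genes
    represent the detectably expressed subset of a transcriptome that
    enters DE testing, so the default of 2.0 counts/cell is typical of that
    subset in droplet data.  ``dispersion`` is the negative-binomial
    dispersion alpha in the RNA-seq convention (variance = mu + alpha mu^2,
    NB size = 1/alpha); 0.5 gives the strong overdispersion and
    zero-inflation-like sparsity of UMI counts.  ``effect_multiplier``
    scales the mean of each cluster's exclusive DE genes (1 = null data).
    """

    n_clusters: int = 5
    cells_per_cluster: int = 40
    n_genes: int = 500
    de_genes_per_cluster: int = 10
    effect_multiplier: float = 4.0
    baseline_mean: float = 2.0
    dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cells_per_cluster < 1 or self.n_genes < 1:
            raise ValueError("cells_per_cluster and n_genes must be >= 1")
        if self.de_genes_per_cluster < 0:
            raise ValueError("de_genes_per_cluster must be >= 0")
        if self.de_genes_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError(
                "de_genes_per_cluster x n_clusters exceeds n_genes; "
                "exclusive DE genes cannot overlap"
            )
        if not self.effect_multiplier >= 1:
            raise ValueError("effect_multiplier must be >= 1")
        if not (self.baseline_mean > 0 and self.dispersion > 0):
            raise ValueError("baseline_mean and dispersion must be > 0")


@dataclass
class SimulatedDataset:
    """Counts, ground truth and normalized matrix from one simulation."""

    counts: np.ndarray
    labels: pd.Series
    matrix: NormalizedExpressionMatrix
    de_genes: dict[str, list[str]]
    gene_means: np.ndarray  # genes x clusters expected counts
    spec: SimulationSpec

    @property
    def solution(self) -> ClusterSolution:
        return ClusterSolution(solution_id="truth", labels=self.labels)


def _normalize(counts: np.ndarray, log_base: float, pc: float) -> np.ndarray:
    lib = counts.sum(axis=0).astype(float)
    median = np.median(lib[lib > 0]) if (lib > 0).any() else 1.0
    sf = np.where(lib > 0, lib / median, 1.0)
    return np.log(counts / sf + pc) / np.log(log_base)


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Draw a cluster-structured NB count matrix and log-normalize it.

    Per-gene baseline means are lognormal around ``baseline_mean``; each
    cluster elevates its own exclusive block of ``de_genes_per_cluster``
    genes by ``effect_multiplier``.  The same seed always yields bitwise
    identical output.
    """
    rng = np.random.default_rng(spec.seed)
    K, n_c, G = spec.n_clusters, spec.cells_per_cluster, spec.n_genes
    gene_ids = pd.Index([f"g{i:04d}" for i in range(G)], name="gene_ids")
    cell_ids = pd.Index(
        [f"cell{i:04d}" for i in range(K * n_c)], name="cell_ids"
    )
    clusters = [f"c{k + 1}" for k in range(K)]
    labels = pd.Series(np.repeat(clusters, n_c), index=cell_ids)

    mu_log = np.log(spec.baseline_mean) - GENE_MEAN_SIGMA**2 / 2
    base = rng.lognormal(mean=mu_log, sigma=GENE_MEAN_SIGMA, size=G)
    gene_means = np.tile(base[:, None], (1, K))
    de_pool = rng.permutation(G)[: K * spec.de_genes_per_cluster]
    de_genes: dict[str, list[str]] = {}
    for k, c in enumerate(clusters):
        block = de_pool[k * spec.de_genes_per_cluster:(k + 1) * spec.de_genes_per_cluster]
        gene_means[block, k] *= spec.effect_multiplier
        de_genes[c] = sorted(gene_ids[block])

    mu = gene_means[:, np.repeat(np.arange(K), n_c)]
    theta = 1.0 / spec.dispersion  # NB size from RNA-seq dispersion alpha
    counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(np.int64)
    values = _normalize(counts, log_base=2.0, pc=1.0)
    matrix = NormalizedExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        log_base=2.0,
        norm_pseudocount=1.0,
    )
    return SimulatedDataset(
        counts=counts,
        labels=labels,
        matrix=matrix,
        de_genes=de_genes,
        gene_means=gene_means,
        spec=spec,
    )


def build_resolution_series(
    m: NormalizedExpressionMatrix,
    true_labels: pd.Series,
    seed: int = 0,
    cluster_counts: list[int] | None = None,
) -> list[ClusterSolution]:
    """Under-, exactly- and over-clustered solutions around a ground truth.

    Coarser solutions merge true clusters following the dendrogram of their
    centroid Euclidean distances (average linkage) in log-normalized
    expression space; finer solutions randomly bisect true clusters, one at
    a time.  ``cluster_counts`` defaults to ``[K-1, K, K+1]``; counts are
    returned in increasing order with solution ids ``k<count>``.
    """
    labels = pd.Series(true_labels).astype(str).reindex(m.cell_ids)
    if labels.isna().any():
        raise ValueError("true_labels do not cover all cells of the matrix")
    clusters = sorted(labels.unique())
    K = len(clusters)
    if K < 2:
        raise ValueError("resolution series requires >= 2 true clusters")
    counts = sorted(cluster_counts or [K - 1, K, K + 1])
    if counts[0] < 1:
        raise ValueError("cluster counts must be >= 1")
    rng = np.random.default_rng(seed)
    X = m.dense()
    centroids = np.stack(
        [X[:, (labels == c).to_numpy()].mean(axis=1) for c in clusters]
    )
    Z = linkage(pdist(centroids), method="average")

    # plan random bisections once so larger counts extend smaller ones
    max_over = max([c for c in counts if c > K], default=K) - K
    split_order = rng.permutation(K)[:max_over] if max_over else np.array([], int)
    split_masks = {}
    for k in split_order:
        cells = labels.index[(labels == clusters[k]).to_numpy()]
        half = rng.permutation(len(cells))[: len(cells) // 2]
        split_masks[clusters[k]] = pd.Index(cells[half])

    solutions: list[ClusterSolution] = []
    for count in counts:
        if count > K + len(split_order):
            raise ValueError(f"cannot build {count} clusters from {K} true clusters")
        lab = labels.copy()
        if count < K:
            merged = fcluster(Z, t=count, criterion="maxclust")
            mapping = {c: f"m{g}" for c, g in zip(clusters, merged)}
            lab = labels.map(mapping)
        elif count > K:
            for k in split_order[: count - K]:
                c = clusters[k]
                in_half = lab.index.isin(split_masks[c]) & (lab == c).to_numpy()
                lab = lab.where(~(lab == c), c + "a")
                lab[in_half] = c + "b"
        solutions.append(ClusterSolution(solution_id=f"k{count}", labels=lab))
    return solutions


def pseudocount_grid(n_clusters: int = 15, max_mean: float = 50.0) -> np.ndarray:
    """Cluster mean abundances for the single-gene pseudocount simulation.

    A deterministic, strictly increasing grid of ``n_clusters`` means from 0
    to ``max_mean`` containing exactly one zero entry.
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 cluster means")
    nonzero = np.linspace(max_mean / (n_clusters - 1), max_mean, n_clusters - 1)
    return np.concatenate([[0.0], nonzero])


def pseudocount_logger_table(
    grid: np.ndarray,
    pseudocounts: tuple[float, ...] = (1.0, 1e-99, 1.0 / 1000),
) -> pd.DataFrame:
    """True vs pseudocount-calculated log2 ratios for all ordered mean pairs.

    ``true_logGER`` is log2(meanA / meanB), +/-inf when exactly one mean is
    zero; ``calc_logGER`` applies each pseudocount.  One row per ordered
    pair (A != B) per pseudocount.
    """
    grid = np.asarray(grid, dtype=float)
    rows = []
    for pc in pseudocounts:
        for i, a in enumerate(grid):
            for j, b in enumerate(grid):
                if i == j:
                    continue
                with np.errstate(divide="ignore"):
                    true = np.log2(a) - np.log2(b) if (a > 0 or b > 0) else 0.0
                rows.append(
                    {
                        "mean_a": a,
                        "mean_b": b,
                        "pseudocount": pc,
                        "true_logGER": true,
                        "calc_logGER": calc_logGER(a, b, pc),
                    }
                )
    return pd.DataFrame(rows)
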