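"""Differential-expression machinery for cluster comparisons.

Significance is assessed with the two-sided Wilcoxon rank-sum
(Mann-Whitney U) test on log-normalized values (ranks are invariant under
the monotone log transform), with false discovery rate controlled per
comparison by the Benjamini-Hochberg step-up procedure.  Two effect sizes
accompany every comparison:

* ``logGER`` — log2 gene expression ratio of the de-logged cluster means,
  computed with a pseudocount equal to the reciprocal of the number of cells
  in the dataset (the smallest possible step in count-based data).  A
  pseudocount of 1 compresses ratios of small means; a vanishing pseudocount
  (1e-99) sends comparisons with zero off to magnitudes in the hundreds; the
  1/N default keeps zero comparisons within the range of the data.
* ``dDR`` — difference in detection rate between the two groups.

Genes enter a test only if they pass a detection-rate threshold (default
10%) in at least one side of the comparison; ``logGER`` (and ``dDR``) are
reported for all genes regardless.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cluster_stats import (
    ClusterGeneStats,
    ClusterSolution,
    NormalizedExpressionMatrix,
    compute_cluster_gene_stats,
)

__all__ = [
    "DEParams",
    "DEResultVsRest",
    "DEResultPairwise",
    "filter_genes_pairwise",
    "wilcoxon_pvalue",
    "bh_adjust",
    "calc_logGER",
    "calc_dDR",
    "calc_de_vs_rest",
    "calc_de_combn",
    "validate_de_table",
    "pair_key",
]

#: largest pooled sample size for which the exact Wilcoxon null is used
EXACT_LIMIT = 50

VS_REST_COLUMNS = ["logGER", "p_value", "FDR", "tested"]
PAIRWISE_COLUMNS = ["logGER", "dDR", "p_value", "FDR", "tested"]


@dataclass
class DEParams:
    """Thresholds and pseudocount governing all DE computations.

    dr_threshold
        Minimum detection rate (in at least one side of a comparison) for a
        gene to be tested. Default 0.10.
    fdr_threshold
        BH FDR below which a gene counts as significant. Default 0.05.
    logger_pseudocount
        Pseudocount for the log2 expression ratio.  ``None`` (default)
        resolves to 1 / (total cells in the dataset) at computation time.
    """

    dr_threshold: float = 0.10
    fdr_threshold: float = 0.05
    logger_pseudocount: float | None = None

    def __post_init__(self):
        if not 0 <= self.dr_threshold <= 1:
            raise ValueError(f"dr_threshold must be in [0,1]: {self.dr_threshold}")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError(f"fdr_threshold must be in (0,1]: {self.fdr_threshold}")
        if self.logger_pseudocount is not None and not self.logger_pseudocount > 0:
            raise ValueError(
                f"logger_pseudocount must be > 0: {self.logger_pseudocount}"
            )

    def resolve_pseudocount(self, total_cells: int) -> float:
        if self.logger_pseudocount is not None:
            return float(self.logger_pseudocount)
        return 1.0 / total_cells

    def to_dict(self) -> dict:
        return {
            "dr_threshold": self.dr_threshold,
            "fdr_threshold": self.fdr_threshold,
            "logger_pseudocount": self.logger_pseudocount,
        }


@dataclass
class DEResultVsRest:
    """One table per cluster: that cluster's cells versus all other cells.

    Each table is indexed by gene with columns ``logGER`` (all genes),
    ``p_value`` / ``FDR`` (NaN for untested genes) and ``tested``.
    """

    tables: dict[str, pd.DataFrame]
    params: DEParams

    @property
    def clusters(self) -> list[str]:
        return sorted(self.tables)


def pair_key(a: str, b: str) -> str:
    """Canonical display key for an unordered cluster pair ("A-B")."""
    a, b = sorted((a, b))
    return f"{a}-{b}"


@dataclass
class DEResultPairwise:
    """One table per unordered cluster pair.

    Tables are keyed internally by the sorted name tuple ``(a, b)``; effect
    sizes are oriented toward the first element (``logGER > 0`` means higher
    in ``a``).  ``named_tables`` exposes the dash-joined string keys used in
    all serialized output.
    """

    tables: dict[tuple[str, str], pd.DataFrame]
    clusters: list[str]
    params: DEParams

    @property
    def named_tables(self) -> dict[str, pd.DataFrame]:
        return {f"{a}-{b}": t for (a, b), t in self.tables.items()}

    def table_for(self, a: str, b: str) -> tuple[pd.DataFrame, int]:
        """Return the pair table and the orientation sign of cluster ``a``.

        Sign is +1 when ``a`` is the pair's first (effect-oriented) cluster,
        -1 otherwise.
        """
        key = tuple(sorted((a, b)))
        if key not in self.tables:
            raise KeyError(f"no pairwise result for clusters {a!r}, {b!r}")
        return self.tables[key], (1 if key[0] == a else -1)

    def pairs_of(self, cluster: str) -> list[tuple[str, str]]:
        return [k for k in self.tables if cluster in k]


def filter_genes_pairwise(
    statsA: pd.Series, statsB: pd.Series, dr_threshold: float
) -> pd.Index:
    """Genes detected at >= ``dr_threshold`` in at least one of two groups."""
    if not statsA.index.equals(statsB.index):
        statsB = statsB.reindex(statsA.index)
        if statsB.isna().any():
            raise ValueError("gene universes of the two groups differ")
    keep = (statsA >= dr_threshold) | (statsB >= dr_threshold)
    return statsA.index[keep.to_numpy()]


def wilcoxon_pvalue(groupA, groupB) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two samples.

    Uses the exact null distribution when the pooled sample size is at most
    ``EXACT_LIMIT`` and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.  Symmetric in argument order.
    """
    a = np.asarray(groupA, dtype=float)
    b = np.asarray(groupB, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group: comparison is untestable")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_LIMIT and tie_free) else "asymptotic"
    return float(
        sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def _rank_sum_pvalues(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for genes x cells blocks.

    Matches :func:`wilcoxon_pvalue` row by row; vectorized when the pooled
    size exceeds the exact-test limit (where every row takes the asymptotic
    path regardless of ties).
    """
    if A.shape[1] == 0 or B.shape[1] == 0:
        raise ValueError("empty group: comparison is untestable")
    if A.shape[0] == 0:
        return np.empty(0)
    if A.shape[1] + B.shape[1] <= EXACT_LIMIT:
        return np.array([wilcoxon_pvalue(a, b) for a, b in zip(A, B)])
    res = sps.mannwhitneyu(A, B, alternative="two-sided", method="asymptotic", axis=1)
    return np.atleast_1d(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def calc_logGER(meanA, meanB, pc: float):
    """log2((meanA + pc) / (meanB + pc)) on the normalized-count scale.

    Antisymmetric under swapping the groups and finite for all non-negative
    means when ``pc > 0``.  Accepts scalars or aligned arrays.
    """
    if not pc > 0:
        raise ValueError(f"logGER pseudocount must be > 0, got {pc}")
    a = np.asarray(meanA, dtype=float)
    b = np.asarray(meanB, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("means on the normalized-count scale must be >= 0")
    out = np.log2(a + pc) - np.log2(b + pc)
    return float(out) if out.ndim == 0 else out


def calc_dDR(drA, drB):
    """Difference in detection rate, drA - drB (in [-1, 1])."""
    out = np.asarray(drA, dtype=float) - np.asarray(drB, dtype=float)
    return float(out) if out.ndim == 0 else out


def _de_table(
    gene_ids: pd.Index,
    logger: np.ndarray,
    tested: pd.Index,
    pvals: np.ndarray,
    ddr: np.ndarray | None = None,
) -> pd.DataFrame:
    df = pd.DataFrame(index=gene_ids)
    df["logGER"] = logger
    if ddr is not None:
        df["dDR"] = ddr
    df["p_value"] = np.nan
    df["FDR"] = np.nan
    df.loc[tested, "p_value"] = pvals
    df.loc[tested, "FDR"] = bh_adjust(pvals)
    df["tested"] = df.index.isin(tested)
    return df


def calc_de_vs_rest(
    m: NormalizedExpressionMatrix,
    s: ClusterSolution,
    stats: ClusterGeneStats | None = None,
    params: DEParams | None = None,
) -> DEResultVsRest:
    """Test each cluster against the pooled remaining cells.

    The detection-rate filter compares the cluster's DR against the pooled
    rest DR; BH correction is applied within each cluster's tested set.
    """
    params = params or DEParams()
    if stats is None:
        stats = compute_cluster_gene_stats(m, s)
    if s.n_clusters < 2:
        raise ValueError("vs-rest DE requires at least 2 clusters")
    pc = params.resolve_pseudocount(m.n_cells)
    labels = s.labels.reindex(m.cell_ids)
    X = m.dense()
    tables: dict[str, pd.DataFrame] = {}
    for c in s.clusters:
        rest = stats.rest_stats(c)
        tested = filter_genes_pairwise(
            stats.frames[c]["DR"], rest["DR"], params.dr_threshold
        )
        in_c = (labels == c).to_numpy()
        rows = m.gene_ids.get_indexer(tested)
        pvals = _rank_sum_pvalues(X[np.ix_(rows, np.flatnonzero(in_c))],
                                  X[np.ix_(rows, np.flatnonzero(~in_c))])
        logger = calc_logGER(stats.frames[c]["MGE"].to_numpy(),
                             rest["MGE"].to_numpy(), pc)
        tables[c] = _de_table(m.gene_ids, logger, tested, pvals)
    return DEResultVsRest(tables=tables, params=params)


def calc_de_combn(
    m: NormalizedExpressionMatrix,
    s: ClusterSolution,
    stats: ClusterGeneStats | None = None,
    params: DEParams | None = None,
) -> DEResultPairwise:
    """Test all unordered cluster pairs.

    Effect sizes are oriented toward the first cluster of each
    name-sorted pair; BH correction is applied within each pair's tested set.
    """
    params = params or DEParams()
    if stats is None:
        stats = compute_cluster_gene_stats(m, s)
    clusters = s.clusters
    if len(clusters) < 2:
        raise ValueError("pairwise DE requires at least 2 clusters")
    pc = params.resolve_pseudocount(m.n_cells)
    labels = s.labels.reindex(m.cell_ids)
    X = m.dense()
    cols = {c: np.flatnonzero((labels == c).to_numpy()) for c in clusters}
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in itertools.combinations(clusters, 2):
        fa, fb = stats.frames[a], stats.frames[b]
        tested = filter_genes_pairwise(fa["DR"], fb["DR"], params.dr_threshold)
        rows = m.gene_ids.get_indexer(tested)
        pvals = _rank_sum_pvalues(X[np.ix_(rows, cols[a])], X[np.ix_(rows, cols[b])])
        logger = calc_logGER(fa["MGE"].to_numpy(), fb["MGE"].to_numpy(), pc)
        ddr = calc_dDR(fa["DR"].to_numpy(), fb["DR"].to_numpy())
        tables[(a, b)] = _de_table(m.gene_ids, logger, tested, pvals, ddr=ddr)
    return DEResultPairwise(tables=tables, clusters=clusters, params=params)


def validate_de_table(df: pd.DataFrame, pairwise: bool = False) -> pd.DataFrame:
    """Schema-check an externally computed DE table (pluggable test results).

    Any test that reports effect size and significance can stand in for the
    built-in Wilcoxon results, provided its table carries the expected
    columns; values are validated, never recomputed.
    """
    required = set(PAIRWISE_COLUMNS if pairwise else VS_REST_COLUMNS)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table is missing columns: {sorted(missing)}")
    tested = df["tested"].astype(bool)
    p = df.loc[tested, "p_value"]
    fdr = df.loc[tested, "FDR"]
    if ((p < 0) | (p > 1)).any() or ((fdr < 0) | (fdr > 1)).any():
        raise ValueError("p_value / FDR outside [0, 1] among tested genes")
    if pairwise and ((df["dDR"] < -1) | (df["dDR"] > 1)).any():
        raise ValueError("dDR outside [-1, 1]")
    return df
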