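"""Expression-matrix data model and cluster-wise gene statistics.

scRNA-seq expression matrices are usually stored log-transformed
(``log_base(normalized count + pseudocount)``).  Averaging log values yields
a geometric-flavoured mean that systematically underestimates the arithmetic
mean of the underlying normalized counts, so every per-cluster statistic in
this package is computed on the *de-logged* (normalized count) scale:

* **DR** — detection rate: proportion of cells in a cluster with a non-zero
  normalized count for the gene.
* **MDGE** — mean detected gene expression: mean normalized count over only
  the cells in which the gene was detected.
* **MGE** — mean gene expression: mean normalized count over *all* cells of
  the cluster.

These satisfy the exact identity ``MGE = DR * MDGE``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "NormalizedExpressionMatrix",
    "ClusterSolution",
    "ClusterGeneStats",
    "delog_matrix",
    "compute_cluster_gene_stats",
    "validate_solution",
]

#: de-logged values above this are considered "detected"
DETECTION_TOL = 1e-12

#: tolerance for de-logged values that should be >= 0 but round below it
NEGATIVE_TOL = 1e-9


def _as_index(ids, what: str) -> pd.Index:
    idx = pd.Index(np.asarray(ids, dtype=object).astype(str), name=what)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")
    return idx


@dataclass
class NormalizedExpressionMatrix:
    """Log-normalized genes x cells expression matrix with its log metadata.

    Parameters
    ----------
    values
        Dense ndarray or scipy sparse matrix of shape (n_genes, n_cells),
        holding ``log_base(normalized count + norm_pseudocount)``.
    gene_ids, cell_ids
        Unique row / column identifiers.
    log_base
        Base of the log transform used in normalization (> 1). Default 2.
    norm_pseudocount
        Pseudocount added before the log transform (>= 0). Default 1.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    log_base: float = 2.0
    norm_pseudocount: float = 1.0

    def __post_init__(self):
        self.gene_ids = _as_index(self.gene_ids, "gene_ids")
        self.cell_ids = _as_index(self.cell_ids, "cell_ids")
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
            data = self.values.data
        else:
            self.values = np.asarray(self.values, dtype=float)
            data = self.values
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if data.size and not np.all(np.isfinite(data)):
            raise ValueError("expression matrix contains non-finite values")
        if not self.log_base > 1:
            raise ValueError(f"log_base must be > 1, got {self.log_base}")
        if self.norm_pseudocount < 0:
            raise ValueError(
                f"norm_pseudocount must be >= 0, got {self.norm_pseudocount}"
            )
        if data.size:
            lo = float(np.min(data)) if not sp.issparse(self.values) else min(
                0.0, float(np.min(data))
            )
            if self.log_base ** lo - self.norm_pseudocount < -NEGATIVE_TOL:
                raise ValueError(
                    "matrix contains log values whose de-logged counts are "
                    "negative; check log_base / norm_pseudocount metadata"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return self.values


@dataclass
class ClusterSolution:
    """Per-cell categorical cluster labels for one clustering solution.

    ``labels`` is a pandas Series indexed by cell id with string cluster
    names as values; labels are always treated as text ("1" != "01").
    """

    solution_id: str
    labels: pd.Series

    def __post_init__(self):
        lab = pd.Series(self.labels)
        if lab.isna().any():
            missing = lab.index[lab.isna()].tolist()
            raise ValueError(f"cells without a cluster label: {missing[:5]}")
        self.labels = lab.astype(str)
        self.labels.index = _as_index(self.labels.index, "cell_ids")
        if self.labels.empty:
            raise ValueError("cluster solution has no cells")

    @property
    def clusters(self) -> list[str]:
        return sorted(self.labels.unique())

    @property
    def n_clusters(self) -> int:
        return self.labels.nunique()

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def cells_of(self, cluster: str) -> pd.Index:
        return self.labels.index[self.labels == cluster]


@dataclass
class ClusterGeneStats:
    """Per (cluster, gene) detection-rate and mean-expression statistics.

    ``frames`` maps cluster name to a DataFrame indexed by gene id with
    columns ``DR``, ``MDGE``, ``MGE`` (de-logged normalized-count scale).
    """

    frames: dict[str, pd.DataFrame]
    n_cells: dict[str, int]
    gene_ids: pd.Index = field(default=None)

    def __post_init__(self):
        if self.gene_ids is None and self.frames:
            self.gene_ids = next(iter(self.frames.values())).index

    @property
    def clusters(self) -> list[str]:
        return sorted(self.frames)

    @property
    def total_cells(self) -> int:
        return int(sum(self.n_cells.values()))

    def metric(self, name: str) -> pd.DataFrame:
        """Genes x clusters frame of one statistic ('DR'|'MDGE'|'MGE')."""
        return pd.DataFrame(
            {c: self.frames[c][name] for c in self.clusters}
        )

    def rest_stats(self, cluster: str) -> pd.DataFrame:
        """Pooled DR and MGE of all cells *outside* ``cluster``.

        Pooling is exact: the rest DR (MGE) is the cell-count-weighted mean
        of the other clusters' DRs (MGEs).
        """
        others = [c for c in self.frames if c != cluster]
        n_rest = sum(self.n_cells[c] for c in others)
        if n_rest == 0:
            raise ValueError(f"no cells outside cluster {cluster!r}")
        dr = sum(self.frames[c]["DR"] * self.n_cells[c] for c in others) / n_rest
        mge = sum(self.frames[c]["MGE"] * self.n_cells[c] for c in others) / n_rest
        out = pd.DataFrame({"DR": dr, "MGE": mge})
        out.attrs["n_cells"] = n_rest
        return out

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (cluster, gene, DR, MDGE, MGE) table for export."""
        parts = []
        for c in self.clusters:
            f = self.frames[c].reset_index()
            f.insert(0, "cluster", c)
            parts.append(f)
        return pd.concat(parts, ignore_index=True)


def delog_matrix(m: NormalizedExpressionMatrix) -> np.ndarray | sp.csr_matrix:
    """Map log-normalized values back to the normalized-count scale.

    Each entry ``e`` maps to ``log_base**e - norm_pseudocount``.  With the
    usual pseudocount of 1 a log value of 0 maps exactly to a count of 0 and
    sparsity is preserved; for other pseudocounts a dense array is returned.
    Tiny negative rounding residues (>= -1e-9) are clipped to zero.
    """
    base, pc = m.log_base, m.norm_pseudocount
    if sp.issparse(m.values) and pc == 1.0:
        out = m.values.copy()
        out.data = np.power(base, out.data) - 1.0
        data = out.data
    else:
        out = np.power(base, m.dense()) - pc
        data = out
    if data.size and not np.all(np.isfinite(data)):
        gi, ci = _first_nonfinite(out)
        raise ValueError(
            "de-logging produced a non-finite value at gene "
            f"{m.gene_ids[gi]!r}, cell {m.cell_ids[ci]!r}"
        )
    np.clip(data, 0.0, None, out=data)
    return out


def _first_nonfinite(x) -> tuple[int, int]:
    if sp.issparse(x):
        x = x.toarray()
    idx = np.argwhere(~np.isfinite(x))
    return tuple(idx[0])


def compute_cluster_gene_stats(
    m: NormalizedExpressionMatrix, s: ClusterSolution
) -> ClusterGeneStats:
    """Compute DR / MDGE / MGE per cluster per gene on the de-logged scale."""
    if set(s.labels.index) != set(m.cell_ids):
        raise ValueError(
            f"cluster solution {s.solution_id!r} does not label the same "
            "cells as the expression matrix"
        )
    labels = s.labels.reindex(m.cell_ids)
    X = delog_matrix(m)
    frames: dict[str, pd.DataFrame] = {}
    n_cells: dict[str, int] = {}
    for c in s.clusters:
        cols = np.flatnonzero((labels == c).to_numpy())
        Xc = X[:, cols]
        if sp.issparse(Xc):
            Xc = Xc.toarray()
        n = len(cols)
        detected = Xc > DETECTION_TOL
        n_det = detected.sum(axis=1)
        total = Xc.sum(axis=1)
        dr = n_det / n
        with np.errstate(invalid="ignore"):
            mdge = np.where(n_det > 0, total / np.maximum(n_det, 1), 0.0)
        frames[c] = pd.DataFrame(
            {"DR": dr, "MDGE": mdge, "MGE": dr * mdge}, index=m.gene_ids
        )
        n_cells[c] = n
    return ClusterGeneStats(frames=frames, n_cells=n_cells, gene_ids=m.gene_ids)


def validate_solution(s: ClusterSolution, min_cells: int = 3) -> list[str]:
    """Warn about clusters too small to test (fewer than ``min_cells`` cells)."""
    warnings: list[str] = []
    for cluster, size in s.cluster_sizes().items():
        if size < min_cells:
            warnings.append(
                f"cluster {cluster!r} in solution {s.solution_id!r} has only "
                f"{size} cell(s) (< {min_cells}); DE results will be unreliable"
            )
    return warnings
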