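"""File I/O: matrices, cluster tables, embeddings, DE exports, archives.

Formats are deliberately open and language-neutral: Matrix Market plus
plain-text ID files (or dense TSV) for expression matrices, TSV for all
tables, JSON for manifests and marker catalogs.  A results archive is a
single deterministic ZIP of that directory layout, replacing a binary
serialization so shared results stay inspectable from any language.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .annotation import CellSetComparison, MarkerCatalog
from .assessment import AssessmentSummary, SolutionAssessment
from .cluster_stats import ClusterSolution, NormalizedExpressionMatrix
from .de_testing import PAIRWISE_COLUMNS, VS_REST_COLUMNS

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_cluster_table",
    "read_embedding",
    "read_marker_catalog",
    "read_cell_set",
    "write_de_tables",
    "ResultsArchive",
    "save_results_archive",
    "load_results_archive",
]

#: fixed ZIP member timestamp for byte-identical archives
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


def _read_ids(path) -> list[str]:
    return [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]


def read_expression_matrix(
    path,
    log_base: float = 2.0,
    norm_pseudocount: float = 1.0,
    gene_ids_path=None,
    cell_ids_path=None,
) -> NormalizedExpressionMatrix:
    """Read a genes x cells log-normalized matrix.

    ``.mtx`` input (Matrix Market triplet, 1-based indices per the format
    standard) requires gene and cell ID files, one ID per line; explicit
    zeros are treated the same as absent entries (undetected).  Any other
    extension is read as dense TSV with gene IDs in the first column and
    cell IDs in the header.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if gene_ids_path is None or cell_ids_path is None:
            raise ValueError("Matrix Market input requires gene and cell ID files")
        values = sp.csr_matrix(spio.mmread(path))
        values.eliminate_zeros()
        genes = _read_ids(gene_ids_path)
        cells = _read_ids(cell_ids_path)
        if values.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {values.shape} does not match ID files "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
    return NormalizedExpressionMatrix(
        values=values,
        gene_ids=pd.Index(genes),
        cell_ids=pd.Index(cells),
        log_base=log_base,
        norm_pseudocount=norm_pseudocount,
    )


def write_expression_matrix(m: NormalizedExpressionMatrix, path) -> None:
    """Write a matrix as dense TSV (gene rows, cell columns)."""
    pd.DataFrame(m.dense(), index=m.gene_ids, columns=m.cell_ids).to_csv(
        path, sep="\t"
    )


def write_counts_mtx(counts, gene_ids, cell_ids, out_dir) -> dict[str, Path]:
    """Write raw counts as Matrix Market plus gene/cell ID text files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "counts.mtx",
        "genes": out_dir / "genes.txt",
        "cells": out_dir / "cells.txt",
    }
    spio.mmwrite(paths["matrix"], sp.coo_matrix(counts))
    paths["genes"].write_text("".join(f"{g}\n" for g in gene_ids))
    paths["cells"].write_text("".join(f"{c}\n" for c in cell_ids))
    return paths


def read_cluster_table(path) -> list[ClusterSolution]:
    """Read a TSV of cluster assignments, one solution per column.

    First column holds cell IDs; labels are read as text (``"1" != "01"``).
    Missing labels are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValueError("cluster table has no solution columns")
    solutions = []
    for col in df.columns:
        if df[col].isna().any():
            missing = df.index[df[col].isna()].tolist()
            raise ValueError(
                f"solution {col!r} is missing labels for cells {missing[:5]}"
            )
        solutions.append(ClusterSolution(solution_id=str(col), labels=df[col]))
    return solutions


def read_embedding(path) -> pd.DataFrame:
    """Read a cells x dims embedding TSV (first column cell IDs).

    Coordinates must be numeric; they are used as-is (no reweighting).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"embedding contains non-numeric entries: {exc}") from exc
    df.index = df.index.astype(str)
    return df


def align_embedding(
    embedding: pd.DataFrame, m: NormalizedExpressionMatrix
) -> pd.DataFrame:
    """Reorder embedding rows to the matrix's cells, erroring on mismatch."""
    unknown = embedding.index.difference(m.cell_ids)
    missing = m.cell_ids.difference(embedding.index)
    if len(unknown) or len(missing):
        raise ValueError(
            f"embedding/matrix cell mismatch: {len(unknown)} unknown, "
            f"{len(missing)} missing (e.g. {([*unknown[:3], *missing[:3]])})"
        )
    return embedding.reindex(m.cell_ids)


def read_marker_catalog(path) -> MarkerCatalog:
    """Read a marker catalog from JSON (type -> [genes]) or two-column TSV."""
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        return MarkerCatalog(types={str(k): list(v) for k, v in data.items()})
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.shape[1] != 2:
        raise ValueError("TSV marker catalog must have exactly two columns")
    types = {
        str(t): g.tolist() for t, g in df.groupby(df.columns[0])[df.columns[1]]
    }
    return MarkerCatalog(types=types)


def read_cell_set(path) -> list[str]:
    """Read a plain list of cell IDs, one per line."""
    return _read_ids(path)


def _format_table(df: pd.DataFrame, pairwise: bool) -> pd.DataFrame:
    cols = PAIRWISE_COLUMNS if pairwise else VS_REST_COLUMNS
    out = df[cols].copy()
    out.index.name = "gene"
    return out.sort_index()


def de_table_files(result) -> dict[str, pd.DataFrame]:
    """Map of file name -> DE table for a solution or cell-set comparison."""
    files: dict[str, pd.DataFrame] = {}
    vs_rest = result.de_vs_rest
    combn = result.de_combn
    if vs_rest is not None:
        for c, t in sorted(vs_rest.tables.items()):
            files[f"vs_rest_{c}.tsv"] = _format_table(t, pairwise=False)
    if combn is not None:
        for key, t in sorted(combn.named_tables.items()):
            files[f"pairwise_{key}.tsv"] = _format_table(t, pairwise=True)
    return files


def write_de_tables(result, out_dir) -> list[Path]:
    """Export all DE tables of a solution/comparison as TSV files.

    One file per comparison, fixed column order, rows sorted by gene name;
    re-export is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in de_table_files(result).items():
        p = out_dir / name
        p.write_bytes(table.to_csv(sep="\t").encode())
        written.append(p)
    return written


def dataset_hash(m: NormalizedExpressionMatrix) -> str:
    h = hashlib.sha256()
    h.update("\n".join(m.gene_ids).encode())
    h.update("\n".join(m.cell_ids).encode())
    h.update(np.ascontiguousarray(m.dense()).tobytes())
    return h.hexdigest()


@dataclass
class ResultsArchive:
    """A loaded results archive: manifest plus raw table bytes."""

    manifest: dict
    files: dict[str, bytes]

    @property
    def solutions(self) -> list[str]:
        return list(self.manifest["solutions"])

    @property
    def default_resolution(self) -> str | None:
        return self.manifest.get("default_resolution")

    def table(self, relpath: str, **kwargs) -> pd.DataFrame:
        if relpath not in self.files:
            raise KeyError(f"archive has no table {relpath!r}")
        kwargs.setdefault("index_col", 0)
        return pd.read_csv(_io.BytesIO(self.files[relpath]), sep="\t", **kwargs)

    def solution_files(self, solution_id: str) -> list[str]:
        prefix = f"solutions/{solution_id}/"
        return sorted(f for f in self.files if f.startswith(prefix))


def _solution_files(assessment: SolutionAssessment) -> dict[str, bytes]:
    files: dict[str, bytes] = {}
    stats = assessment.stats.to_long_frame().sort_values(
        ["cluster", "gene_ids"], kind="mergesort"
    )
    files["stats.tsv"] = stats.to_csv(sep="\t", index=False).encode()
    for name, table in de_table_files(assessment).items():
        files[name] = table.to_csv(sep="\t").encode()
    if assessment.silhouette is not None:
        sil = pd.DataFrame(
            {
                "cluster": assessment.solution.labels,
                "width": assessment.silhouette.widths,
            }
        )
        sil.index.name = "cell"
        files["silhouette.tsv"] = sil.to_csv(sep="\t").encode()
    return files


def save_results_archive(
    assessments: list[SolutionAssessment],
    summary: AssessmentSummary,
    path,
    matrix: NormalizedExpressionMatrix | None = None,
    default_resolution: str | None = None,
    comparisons: list[CellSetComparison] | None = None,
) -> Path:
    """Save a whole assessment run as one deterministic ZIP archive.

    The manifest records the dataset hash, parameters, solution IDs, the
    saved default resolution and per-file SHA-256 digests; identical inputs
    always produce byte-identical archives (fixed member timestamps).
    """
    path = Path(path)
    ids = [assessment.solution_id for assessment in assessments]
    if default_resolution is not None and default_resolution not in ids:
        raise ValueError(
            f"default resolution {default_resolution!r} is not a saved solution"
        )
    files: dict[str, bytes] = {}
    for assessment in assessments:
        for name, data in _solution_files(assessment).items():
            files[f"solutions/{assessment.solution_id}/{name}"] = data
    for cmp_ in comparisons or []:
        for name, table in de_table_files(cmp_).items():
            files[f"comparisons/{cmp_.comparison_id}/{name}"] = table.to_csv(
                sep="\t"
            ).encode()
    files["summary.tsv"] = summary.table().to_csv(sep="\t", index=False).encode()
    files["summary_clusters.json"] = json.dumps(
        summary.per_cluster_json(), indent=1, sort_keys=True
    ).encode()
    params = assessments[0].params.to_dict() if assessments else {}
    manifest = {
        "format_version": 1,
        "dataset_hash": dataset_hash(matrix) if matrix is not None else None,
        "params": params,
        "solutions": ids,
        "default_resolution": default_resolution,
        "comparisons": [c.comparison_id for c in comparisons or []],
        "files": {
            name: hashlib.sha256(data).hexdigest() for name, data in sorted(files.items())
        },
    }
    manifest_bytes = json.dumps(manifest, indent=1, sort_keys=True).encode()
    path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in ["manifest.json"] + sorted(files):
            data = manifest_bytes if name == "manifest.json" else files[name]
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, data)
    return path


def load_results_archive(path) -> ResultsArchive:
    """Load an archive, verifying every manifest entry against its file.

    A missing, extra or modified table is an error naming the offending
    member.
    """
    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())
        if "manifest.json" not in names:
            raise ValueError("archive has no manifest.json")
        manifest = json.loads(zf.read("manifest.json"))
        files: dict[str, bytes] = {}
        listed = manifest.get("files", {})
        for name, digest in listed.items():
            if name not in names:
                raise ValueError(f"archive is missing table {name!r}")
            data = zf.read(name)
            if hashlib.sha256(data).hexdigest() != digest:
                raise ValueError(f"archive table {name!r} does not match manifest")
            files[name] = data
        extra = names - set(listed) - {"manifest.json"}
        if extra:
            raise ValueError(f"archive contains unlisted files: {sorted(extra)[:5]}")
    for sid in manifest.get("solutions", []):
        if not any(f.startswith(f"solutions/{sid}/") for f in files):
            raise ValueError(f"manifest lists solution {sid!r} with no tables")
    default = manifest.get("default_resolution")
    if default is not None and default not in manifest.get("solutions", []):
        raise ValueError(f"saved default resolution {default!r} is unknown")
    return ResultsArchive(manifest=manifest, files=files)
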