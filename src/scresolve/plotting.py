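"""Static vector-graphic exports of the assessment figures.

Each figure has a companion ``*_data`` helper returning the exact numbers
plotted, so the plotted quantities are testable independently of aesthetics:

* resolution-assessment boxplots (neighbour-DE gene counts per solution,
  arranged by cluster count),
* per-solution silhouette plot,
* marker-gene dot plot (dot size = detection rate, colour = mean detected
  expression),
* per-cluster detection-rate vs mean-detected-expression scatter.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .assessment import AssessmentSummary, SolutionAssessment, de_marker

__all__ = [
    "assessment_boxplot_data",
    "dot_plot_data",
    "render_static_figures",
]

_SAVEFIG = {"format": "svg", "metadata": {"Date": None}}


def assessment_boxplot_data(summary: AssessmentSummary) -> pd.DataFrame:
    """Long table of per-cluster neighbour-DE counts per solution."""
    rows = []
    for r in summary.rows:
        for cluster, count in sorted(r.neighb_counts.items()):
            rows.append(
                {
                    "solution_id": r.solution_id,
                    "n_clusters": r.n_clusters,
                    "cluster": cluster,
                    "neighb_count": count,
                }
            )
    return pd.DataFrame(rows, columns=["solution_id", "n_clusters", "cluster", "neighb_count"])


def dot_plot_data(assessment: SolutionAssessment, genes) -> pd.DataFrame:
    """Long (cluster, gene, DR, MDGE) table behind the dot plot."""
    genes = [g for g in genes if g in assessment.stats.gene_ids]
    rows = []
    for c in assessment.stats.clusters:
        f = assessment.stats.frames[c]
        for g in genes:
            rows.append(
                {"cluster": c, "gene": g, "DR": f.at[g, "DR"], "MDGE": f.at[g, "MDGE"]}
            )
    return pd.DataFrame(rows, columns=["cluster", "gene", "DR", "MDGE"])


def _plot_assessment(summary: AssessmentSummary, path: Path) -> None:
    data = assessment_boxplot_data(summary)
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(data):
        groups = [
            (n, g["neighb_count"].to_numpy())
            for n, g in data.groupby("n_clusters", sort=True)
        ]
        ax.boxplot([g for _, g in groups], positions=[n for n, _ in groups])
    ax.set_xlabel("number of clusters")
    ax.set_ylabel("positively DE genes vs nearest neighbour")
    fig.savefig(path, **_SAVEFIG)
    plt.close(fig)


def _plot_silhouette(assessment: SolutionAssessment, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 6))
    sil = assessment.silhouette
    if sil is not None:
        order = (
            pd.DataFrame({"c": assessment.solution.labels, "w": sil.widths})
            .sort_values(["c", "w"], ascending=[True, False], kind="mergesort")
        )
        ax.barh(np.arange(len(order)), order["w"].to_numpy(), height=1.0)
        ax.set_xlabel("silhouette width")
        ax.set_title(f"{assessment.solution_id}: mean width {sil.overall_mean:.3f}")
    fig.savefig(path, **_SAVEFIG)
    plt.close(fig)


def _plot_dot(assessment: SolutionAssessment, path: Path, top_n: int = 10) -> None:
    markers = de_marker(assessment) if assessment.de_combn is not None else {}
    genes: list[str] = []
    for c in sorted(markers):
        ranked = assessment.stats.frames[c].loc[markers[c]].sort_values(
            "MGE", ascending=False
        )
        genes.extend(g for g in ranked.index[:top_n] if g not in genes)
    data = dot_plot_data(assessment, genes)
    fig, ax = plt.subplots(figsize=(max(4, 0.25 * len(genes) + 2), 4))
    if len(data):
        clusters = sorted(data["cluster"].unique())
        gx = {g: i for i, g in enumerate(genes)}
        cy = {c: i for i, c in enumerate(clusters)}
        ax.scatter(
            [gx[g] for g in data["gene"]],
            [cy[c] for c in data["cluster"]],
            s=10 + 200 * data["DR"].to_numpy(),
            c=data["MDGE"].to_numpy(),
            cmap="viridis",
        )
        ax.set_xticks(range(len(genes)), genes, rotation=90, fontsize=6)
        ax.set_yticks(range(len(clusters)), clusters)
    else:
        ax.set_title("no marker genes at this resolution")
    fig.savefig(path, **_SAVEFIG)
    plt.close(fig)


def _plot_dr_scatter(assessment: SolutionAssessment, path: Path) -> None:
    clusters = assessment.stats.clusters
    fig, axes = plt.subplots(
        1, len(clusters), figsize=(3 * len(clusters), 3), squeeze=False
    )
    for ax, c in zip(axes[0], clusters):
        f = assessment.stats.frames[c]
        ax.scatter(f["DR"], f["MDGE"], s=4, alpha=0.5)
        ax.set_title(c, fontsize=8)
        ax.set_xlabel("DR")
        ax.set_ylabel("MDGE")
    fig.tight_layout()
    fig.savefig(path, **_SAVEFIG)
    plt.close(fig)


def render_static_figures(
    assessments: list[SolutionAssessment], summary: AssessmentSummary, out_dir
) -> list[Path]:
    """Write the assessment figure plus per-solution figures as SVG."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = [out_dir / "assessment.svg"]
    _plot_assessment(summary, written[0])
    for assessment in assessments:
        sid = assessment.solution_id
        if assessment.silhouette is not None:
            p = out_dir / f"silhouette_{sid}.svg"
            _plot_silhouette(assessment, p)
            written.append(p)
        p = out_dir / f"dotplot_{sid}.svg"
        _plot_dot(assessment, p)
        written.append(p)
        p = out_dir / f"dr_scatter_{sid}.svg"
        _plot_dr_scatter(assessment, p)
        written.append(p)
    return written
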