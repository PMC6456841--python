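import numpy as np
import pandas as pd
import pytest

import scresolve as sr
from scresolve.assessment import assess_solution

from oracles import brute_silhouette


def de_table(fdr, logger, genes=None):
    genes = genes or [f"g{i}" for i in range(len(fdr))]
    fdr = np.asarray(fdr, dtype=float)
    return pd.DataFrame(
        {
            "logGER": np.asarray(logger, dtype=float),
            "dDR": np.zeros(len(fdr)),
            "p_value": fdr / 2,
            "FDR": fdr,
            "tested": ~np.isnan(fdr),
        },
        index=pd.Index(genes, name="gene"),
    )


def pairwise_from_counts(counts: dict[tuple[str, str], int], n_genes=10):
    """Build a DEResultPairwise whose per-pair significant counts are given."""
    tables = {}
    clusters = sorted({c for pair in counts for c in pair})
    for pair, k in counts.items():
        fdr = np.ones(n_genes)
        fdr[:k] = 0.01
        tables[tuple(sorted(pair))] = de_table(fdr, np.ones(n_genes))
    return sr.DEResultPairwise(
        tables=tables, clusters=clusters, params=sr.DEParams()
    )


class TestCountSignificant:
    def test_direction_handling(self):
        t = de_table([0.01, 0.01, 0.01], [2.0, 1.0, -1.0])
        assert sr.count_significant_genes(t, 0.05, "both") == 3
        assert sr.count_significant_genes(t, 0.05, "positive") == 2
        assert sr.count_significant_genes(t, 0.05, "positive", sign=-1) == 1

    def test_empty_and_all_null(self):
        assert sr.count_significant_genes(de_table([], []), 0.05) == 0
        assert (
            sr.count_significant_genes(de_table([1.0, 1.0], [1, 1]), 0.05) == 0
        )

    def test_untested_genes_never_count(self):
        t = de_table([np.nan, 0.01], [3.0, 3.0])
        assert sr.count_significant_genes(t, 0.05) == 1


class TestNearestNeighbours:
    def test_argmin_by_de_count(self):
        combn = pairwise_from_counts(
            {("A", "B"): 5, ("A", "C"): 0, ("B", "C"): 2}
        )
        nb = sr.find_nearest_neighbors(combn)
        assert nb == {"A": "C", "B": "C", "C": "A"}

    def test_two_clusters_are_mutual_neighbours(self):
        combn = pairwise_from_counts({("A", "B"): 3})
        assert sr.find_nearest_neighbors(combn) == {"A": "B", "B": "A"}

    def test_tie_breaks_by_name_order(self):
        combn = pairwise_from_counts(
            {("A", "B"): 2, ("A", "C"): 2, ("B", "C"): 9}
        )
        assert sr.find_nearest_neighbors(combn)["A"] == "B"


def assessment_from_combn(combn):
    labels = pd.Series(
        list(combn.clusters), index=[f"cell_{c}" for c in combn.clusters]
    )
    return sr.SolutionAssessment(
        solution_id="fixture",
        solution=sr.ClusterSolution("fixture", labels),
        stats=None,
        de_vs_rest=None,
        de_combn=combn,
        silhouette=None,
        params=sr.DEParams(),
    )


class TestNeighbourAndMarkerSets:
    def test_all_null_pair_gives_empty_sets(self):
        combn = pairwise_from_counts({("A", "B"): 0})
        sets = sr.de_neighb(assessment_from_combn(combn))
        assert len(sets["A"]) == 0 and len(sets["B"]) == 0

    def test_single_elevated_gene_found_in_high_cluster_only(self):
        fdr = np.ones(10)
        fdr[0] = 0.001
        logger = np.zeros(10)
        logger[0] = 2.0  # positive toward first-named cluster A
        combn = sr.DEResultPairwise(
            tables={("A", "B"): de_table(fdr, logger)},
            clusters=["A", "B"],
            params=sr.DEParams(),
        )
        sets = sr.de_neighb(assessment_from_combn(combn))
        assert list(sets["A"]) == ["g0"]
        assert len(sets["B"]) == 0

    def test_two_cluster_markers_equal_neighbour_set(self, sim_dataset):
        sols = sr.build_resolution_series(
            sim_dataset.matrix, sim_dataset.labels, seed=0, cluster_counts=[2]
        )
        assessment = assess_solution(sim_dataset.matrix, sols[0])
        nb, mk = sr.de_neighb(assessment), sr.de_marker(assessment)
        for c in nb:
            assert set(nb[c]) == set(mk[c])

    def test_gene_must_win_every_pair_to_be_marker(self):
        # g0 positive/significant vs B but flat vs C -> not a marker of A
        fdr_ab = np.ones(5); fdr_ab[0] = 0.001
        logger_ab = np.zeros(5); logger_ab[0] = 2.0
        combn = sr.DEResultPairwise(
            tables={
                ("A", "B"): de_table(fdr_ab, logger_ab),
                ("A", "C"): de_table(np.ones(5), np.zeros(5)),
                ("B", "C"): de_table(np.ones(5), np.zeros(5)),
            },
            clusters=["A", "B", "C"],
            params=sr.DEParams(),
        )
        assert len(sr.de_marker(assessment_from_combn(combn))["A"]) == 0

    def test_markers_subset_of_neighbour_genes(self, sim_assessment):
        """The marker criterion quantifies over a superset of pairs."""
        nb, mk = sr.de_neighb(sim_assessment), sr.de_marker(sim_assessment)
        for c in mk:
            assert set(mk[c]) <= set(nb[c])


class TestSilhouette:
    def test_line_example(self):
        emb = pd.DataFrame({"x": [0.0, 1.0, 10.0, 11.0]}, index=list("abcd"))
        s = sr.ClusterSolution(
            "line", pd.Series(["1", "1", "2", "2"], index=list("abcd"))
        )
        res = sr.silhouette_widths(emb, s)
        assert res.widths["a"] == pytest.approx(9.5 / 10.5)
        assert res.widths.between(-1, 1).all()

    def test_coincident_points_and_singletons_get_zero(self):
        emb = pd.DataFrame(np.zeros((4, 2)), index=list("abcd"))
        s = sr.ClusterSolution(
            "z", pd.Series(["1", "1", "2", "2"], index=list("abcd"))
        )
        assert (sr.silhouette_widths(emb, s).widths == 0).all()
        emb2 = pd.DataFrame({"x": [0.0, 1.0, 5.0]}, index=list("abc"))
        s2 = sr.ClusterSolution(
            "s", pd.Series(["1", "1", "2"], index=list("abc"))
        )
        assert sr.silhouette_widths(emb2, s2).widths["c"] == 0.0

    def test_cell_mismatch_rejected(self):
        emb = pd.DataFrame({"x": [0.0, 1.0]}, index=["a", "b"])
        s = sr.ClusterSolution("s", pd.Series(["1", "2"], index=["a", "zzz"]))
        with pytest.raises(ValueError, match="match"):
            sr.silhouette_widths(emb, s)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 40)
        coords = rng.normal(size=(n, rng.integers(1, 6)))
        labels = rng.integers(0, rng.integers(2, 5), size=n).astype(str)
        if len(set(labels)) < 2:
            labels[0] = "forced"
        cells = [f"c{i}" for i in range(n)]
        res = sr.silhouette_widths(
            pd.DataFrame(coords, index=cells),
            sr.ClusterSolution("r", pd.Series(labels, index=cells)),
        )
        np.testing.assert_allclose(
            res.widths.to_numpy(), brute_silhouette(coords, labels), atol=1e-9
        )

    def test_matches_sklearn_when_all_clusters_multi_cell(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(42)
        coords = np.concatenate(
            [rng.normal(0, 1, (15, 3)), rng.normal(4, 1, (15, 3))]
        )
        labels = np.array(["a"] * 15 + ["b"] * 15)
        cells = [f"c{i}" for i in range(30)]
        res = sr.silhouette_widths(
            pd.DataFrame(coords, index=cells),
            sr.ClusterSolution("s", pd.Series(labels, index=cells)),
        )
        np.testing.assert_allclose(
            res.widths.to_numpy(),
            silhouette_samples(coords, labels),
            atol=1e-9,
        )


class TestSummarizeAndSweep:
    def test_pass_flag_requires_every_cluster(self):
        # significant genes point toward both sides of the pair -> pass
        t = de_table([0.01, 0.01, 1.0], [2.0, -1.5, 0.0])
        good = assessment_from_combn(
            sr.DEResultPairwise(
                tables={("A", "B"): t}, clusters=["A", "B"], params=sr.DEParams()
            )
        )
        assert sr.summarize_resolution(good).passed_neighbour_check
        # significant genes exist but none positive toward either side
        t = de_table([0.01] * 4, [0.0] * 4)
        bad = assessment_from_combn(
            sr.DEResultPairwise(
                tables={("A", "B"): t}, clusters=["A", "B"], params=sr.DEParams()
            )
        )
        assert not sr.summarize_resolution(bad).passed_neighbour_check

    def test_counts_match_hand_tally(self):
        combn = pairwise_from_counts(
            {("A", "B"): 1, ("A", "C"): 4, ("B", "C"): 2}
        )
        row = sr.summarize_resolution(assessment_from_combn(combn))
        # every significant gene in these fixtures is positive toward the
        # first-named cluster, so counts follow each cluster's neighbour pair
        assert row.neighbours == {"A": "B", "B": "A", "C": "B"}
        assert row.neighb_counts == {"A": 1, "B": 0, "C": 0}
        assert not row.passed_neighbour_check

    def test_sweep_orders_and_stops(self, sim_dataset):
        sols = sr.build_resolution_series(
            sim_dataset.matrix, sim_dataset.labels, seed=3,
            cluster_counts=[3, 5, 6],
        )
        assessments, summary = sr.sweep_resolutions(
            sim_dataset.matrix, sols[::-1], stop_on_loss=True
        )
        t = summary.table()
        assert list(t["n_clusters"]) == sorted(t["n_clusters"])
        if not t["passed_neighbour_check"].all():
            # the failing solution is retained and is the last processed
            assert not t["passed_neighbour_check"].iloc[-1]

    def test_sweep_without_stop_processes_everything(self, sim_dataset):
        sols = sr.build_resolution_series(
            sim_dataset.matrix, sim_dataset.labels, seed=3,
            cluster_counts=[5, 6],
        )
        assessments, summary = sr.sweep_resolutions(
            sim_dataset.matrix, sols, stop_on_loss=False
        )
        assert len(assessments) == 2

    def test_single_cluster_solution_summarized_without_de(self, sim_dataset):
        labels = pd.Series("all", index=sim_dataset.matrix.cell_ids)
        assessments, summary = sr.sweep_resolutions(
            sim_dataset.matrix, [sr.ClusterSolution("k1", labels)]
        )
        row = summary.rows[0]
        assert assessments[0].de_combn is None
        assert row.n_clusters == 1 and row.passed_neighbour_check
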