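import numpy as np
import pandas as pd
import pytest

import scresolve as sr


def log2p1(x):
    return np.log2(np.asarray(x, dtype=float) + 1.0)


@pytest.fixture
def tiny_matrix():
    """4 genes x 6 cells, log2(count+1), hand-constructed counts."""
    counts = np.array(
        [
            [0, 0, 2, 4, 0, 0],  # detected in half of cluster A only
            [1, 1, 1, 1, 1, 1],  # flat everywhere
            [0, 0, 0, 0, 5, 7],  # cluster B exclusive
            [0, 0, 0, 0, 0, 0],  # never detected
        ]
    )
    return sr.NormalizedExpressionMatrix(
        values=log2p1(counts),
        gene_ids=pd.Index(["g1", "g2", "g3", "g4"]),
        cell_ids=pd.Index([f"c{i}" for i in range(6)]),
    )


@pytest.fixture
def tiny_solution(tiny_matrix):
    labels = pd.Series(
        ["A", "A", "A", "A", "B", "B"], index=tiny_matrix.cell_ids
    )
    return sr.ClusterSolution(solution_id="tiny", labels=labels)


@pytest.fixture(scope="session")
def sim_dataset():
    """Default 5-cluster simulation shared across read-only tests."""
    return sr.simulate_dataset(sr.SimulationSpec(seed=7))


@pytest.fixture(scope="session")
def sim_assessment(sim_dataset):
    """Full assessment bundle for the true 5-cluster solution."""
    return sr.assess_solution(sim_dataset.matrix, sim_dataset.solution)
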