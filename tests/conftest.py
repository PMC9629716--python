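import numpy as np
import pandas as pd
import pytest

import lea


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic dataset with all planted effects (shared, read-only)."""
    spec = lea.SyntheticSpec(
        n_donors=6, cells_per_donor=300, n_wells=3, cells_per_well=800,
        n_genes=40, n_signal_genes=3,
    )
    return lea.simulate(spec, seed=20240917)


@pytest.fixture(scope="session")
def small_index(small_dataset):
    return lea.build_knn(small_dataset["probabilities"], k=60)


@pytest.fixture()
def tiny_pm():
    """Three cells, two well-separated classes."""
    values = np.array([[0.9, 0.1], [0.85, 0.15], [0.05, 0.95]])
    return lea.ProbabilityMatrix(["a", "b", "c"], values, ["c0", "c1"])


def make_index(neighbor_ids, cell_ids=None, metric="euclidean"):
    nbr = np.asarray(neighbor_ids, dtype=np.int64)
    ids = np.arange(nbr.shape[0]) if cell_ids is None else np.asarray(cell_ids)
    return lea.NeighborhoodIndex(
        k=nbr.shape[1], metric=metric, neighbor_ids=nbr, cell_ids=ids
    )


@pytest.fixture()
def handmade_index():
    """11 cells; cell 0's neighborhood is all of cells 1..10."""
    n = 11
    nbr = np.array([[j for j in range(n) if j != i][:10] for i in range(n)])
    return make_index(nbr, cell_ids=[f"c{i}" for i in range(n)])
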