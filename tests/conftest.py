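import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hepaging.io_core import CountMatrix, NormalizedMatrix
from hepaging.simulate import CellTypeSpec, SimConfig, simulate_counts


def make_count_matrix(arr, gene_ids=None, cell_ids=None) -> CountMatrix:
    arr = np.asarray(arr)
    gene_ids = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(arr.shape[1])]
    return CountMatrix(sp.csr_matrix(arr), gene_ids, cell_ids)


def make_normalized(arr, gene_ids=None, cell_ids=None) -> NormalizedMatrix:
    arr = np.asarray(arr, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(arr.shape[1])]
    return NormalizedMatrix(sp.csr_matrix(arr), gene_ids, cell_ids)


def make_meta(cell_ids, groups, cell_types=None, samples=None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "sample_id": samples or [f"{g}_s1" for g in groups],
            "group": list(groups),
            "cell_type": cell_types if cell_types is not None else ["T"] * len(cell_ids),
        }
    )


@pytest.fixture(scope="session")
def small_sim():
    """Two cell types, injected markers, no aging effects. Shared across tests."""
    config = SimConfig(
        n_genes=120,
        cell_types=[
            CellTypeSpec("Hep", n_young=60, n_aged=60, marker_genes=6, marker_lfc=2.0),
            CellTypeSpec("HSC", n_young=40, n_aged=40, marker_genes=6, marker_lfc=2.0),
        ],
        baseline_log_mean=1.0,
        baseline_log_sd=0.6,
        nb_dispersion=10.0,
        seed=7,
    )
    cm, meta, truth = simulate_counts(config)
    return cm, meta, truth
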