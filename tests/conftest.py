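import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from retinotopo import CellDataset, normalize_counts
from retinotopo.axis_scoring import compute_axis_scores
from retinotopo.io_core import get_preset
from retinotopo.synth_data import make_benchmark_suite
from retinotopo.topo_grid import build_grid


def make_toy_dataset(counts, genes=None, embryos=None) -> CellDataset:
    """Small dense-count CellDataset for unit tests."""
    counts = np.asarray(counts)
    n, m = counts.shape
    genes = genes or [f"g{j}" for j in range(m)]
    cells = [f"c{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "embryo_id": embryos or ["e0"] * n,
            "library_id": ["lib0"] * n,
            "species": "chicken",
        },
        index=pd.Index(cells, name="cell_id"),
    )
    return CellDataset(
        counts=sp.csr_matrix(counts),
        cells=np.array(cells, dtype=object),
        genes=np.array(genes, dtype=object),
        meta=meta,
    )


@pytest.fixture(scope="session")
def small_bench():
    """Cheap benchmark (4,000 cells, 60 decoys) for unit-level checks."""
    bundle = make_benchmark_suite(seed=7, n_cells=4000, n_decoys=60)
    scores = compute_axis_scores(bundle.dataset, bundle.gene_sets, seed=7)
    grid = build_grid(scores, bundle.dataset, get_preset("chicken"))
    return bundle, scores, grid


@pytest.fixture(scope="session")
def bench():
    """Full stated-world benchmark: 20,000 cells, 500 decoys, seed 0."""
    bundle = make_benchmark_suite(seed=0)
    scores = compute_axis_scores(bundle.dataset, bundle.gene_sets, seed=0)
    grid = build_grid(scores, bundle.dataset, get_preset("chicken"))
    return bundle, scores, grid
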