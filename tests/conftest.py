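import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import anndata as ad

from perturbcircuit import SimulationConfig, generate_truth, simulate_counts


SMALL_CONFIG = SimulationConfig(
    n_genes=400,
    n_targets=6,
    n_programs=4,
    cells_per_guide=60,
    n_control_cells=150,
    doublet_rate=0.15,
    background_fraction=0.2,
)


@pytest.fixture(scope="session")
def small_truth():
    return generate_truth(SMALL_CONFIG, seed=42)


@pytest.fixture(scope="session")
def small_screen(small_truth):
    """Counts + guide table for a small simulated screen (shared, read-only)."""
    adata, guides = simulate_counts(small_truth, seed=42)
    return adata, guides


@pytest.fixture()
def hand_counts():
    """Ten hand-written cells with known QC metrics.

    Genes: G1, G2, MT-A (mitochondrial). Expected metrics are hand-computed
    in the table below and in the tests that use this fixture.
    """
    counts = np.array([
        [0, 0, 5],      # 1 gene detected, total 5, mito 1.0
        [10, 10, 0],    # 2 genes, total 20, mito 0.0
        [1, 2, 3],      # 3 genes, total 6, mito 0.5
        [0, 0, 0],      # 0 genes, total 0, mito 0.0
        [100, 0, 0],    # 1 gene, total 100, mito 0.0
        [50, 50, 25],   # 3 genes, total 125, mito 0.2
        [7, 0, 3],      # 2 genes, total 10, mito 0.3
        [1, 1, 0],      # 2 genes, total 2, mito 0.0
        [0, 30, 10],    # 2 genes, total 40, mito 0.25
        [20, 20, 10],   # 3 genes, total 50, mito 0.2
    ])
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=[f"C{i}" for i in range(10)]),
        var=pd.DataFrame(index=["G1", "G2", "MT-A"]),
    )
    return adata
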