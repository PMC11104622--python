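"""Shared fixtures: small hand-built matrices and simulated datasets."""

import numpy as np
import pytest
import scipy.sparse as sp

from crosstalk import (
    CellMatrix,
    LRDatabase,
    LRRecord,
    PlantedLR,
    SimulationConfig,
    SpotMatrix,
    simulate_paired,
)


@pytest.fixture
def tiny_cells():
    """3 cells x 2 genes with 4 stored entries."""
    counts = sp.csr_matrix(np.array([[1, 0], [2, 3], [0, 4]]))
    return CellMatrix(
        counts=counts,
        gene_ids=["GENE_A", "GENE_B"],
        cell_ids=["bc1", "bc2", "bc3"],
        cell_type=np.array(["T1", "T1", "T2"], dtype=object),
        condition=np.array(["healthy", "healthy", "disease"], dtype=object),
        sample_id=np.array(["s1", "s1", "s2"], dtype=object),
    )


@pytest.fixture
def grid_spots():
    """4 spots on a 2x2 grid, 2 genes."""
    counts = sp.csr_matrix(np.array([[5, 1], [0, 2], [3, 3], [1, 0]]))
    return SpotMatrix(
        counts=counts,
        gene_ids=["GENE_A", "GENE_B"],
        spot_ids=["sp1", "sp2", "sp3", "sp4"],
        xy=np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float),
        sample_id=np.array(["sl1"] * 4, dtype=object),
        condition=np.array(["healthy"] * 4, dtype=object),
    )


@pytest.fixture
def mini_db():
    return LRDatabase(
        [
            LRRecord("SPP1_ITGAVITGB1", "SPP1", ("ITGAV", "ITGB1"), "SPP1"),
            LRRecord("NRG3_ERBB4", "NRG3", ("ERBB4",), "NRG"),
        ]
    )


def small_sim_config(seed=0, **kw):
    """A fast simulation config shared by several tests."""
    defaults = dict(
        n_cell_types=5,
        n_genes=200,
        n_cells_per_type_per_condition=100,
        n_spots_per_sample=64,
        n_samples_per_condition=1,
        seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_paired():
    """One small paired dataset reused by read-only tests."""
    cfg = small_sim_config(seed=11)
    cells, spots, truth = simulate_paired(cfg)
    return cfg, cells, spots, truth
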