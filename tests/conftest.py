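import numpy as np
import pytest

from enclasc import ExpressionDataset, SimulationConfig, simulate


@pytest.fixture
def toy_dataset():
    """4 cells × 3 genes with labels; values chosen to exercise zeros."""
    values = np.array(
        [
            [0.0, 2.0, 1.0],
            [1.0, 0.0, 1.0],
            [3.0, 5.0, 1.0],
            [0.0, 1.0, 1.0],
        ]
    )
    return ExpressionDataset(
        values,
        gene_names=["geneA", "geneB", "geneC"],
        cell_ids=["c1", "c2", "c3", "c4"],
        labels=["alpha", "alpha", "beta", "beta"],
    )


@pytest.fixture(scope="session")
def small_population():
    """A small labelled synthetic population shared by pipeline tests."""
    config = SimulationConfig(
        n_cells=300,
        n_genes=120,
        class_proportions=(0.4, 0.3, 0.3),
        n_marker_genes_per_class=10,
        seed=11,
    )
    return simulate(config)
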