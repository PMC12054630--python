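import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from anchorseek.preprocess import CountMatrix
from anchorseek.synthdata import SimulationConfig, simulate_pair


@pytest.fixture
def toy_counts():
    """4 genes x 4 cells with known totals (0, 5, 50, 500)."""
    x = np.array(
        [
            [0, 1, 10, 100],
            [0, 2, 20, 200],
            [0, 2, 20, 200],
            [0, 0, 0, 0],
        ]
    )
    genes = ["g1", "g2", "g3", "g4"]
    barcodes = ["c1", "c2", "c3", "c4"]
    return CountMatrix(genes, barcodes, sp.csr_matrix(x))


@pytest.fixture
def toy_meta():
    return pd.DataFrame(
        {
            "barcode": ["c1", "c2", "c3", "c4"],
            "species": "mouse",
            "cell_type": ["CM", "CM", "CM", "FB"],
            "condition": ["control", "stressed", "stressed", "control"],
            "sample": "s1",
        }
    )


@pytest.fixture(scope="session")
def small_pair():
    """Session-scoped small paired simulation with strong signal."""
    cfg = SimulationConfig(
        n_genes=300, n_cells_per_group=100, n_planted=20, effect_size=1.0,
        homolog_fraction=0.9, seed=7,
    )
    (ca, ma), (cb, mb), hom, truth = simulate_pair(cfg)
    return cfg, (ca, ma), (cb, mb), hom, truth
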