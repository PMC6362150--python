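import numpy as np
import pandas as pd
import pytest

from imprintkit import SimulationConfig, simulate_dataset
from imprintkit.counts import AllelicCounts


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated dataset (2,000 genes, 40 spike-ins) shared by
    read-only tests."""
    config = SimulationConfig(
        n_genes=2000,
        spike_design=(
            ("strong_MEG", 10, 0.99),
            ("weak_MEG", 10, 0.85),
            ("strong_PEG", 10, 0.34),
            ("weak_PEG", 10, 0.48),
        ),
        seed=42,
    )
    return simulate_dataset(config)


@pytest.fixture
def toy_counts():
    """A 4-gene, 2-cross table with hand-picked counts."""
    return AllelicCounts(
        pd.DataFrame(
            {
                "maternal_1": [20, 40, 3, 0],
                "paternal_1": [10, 20, 2, 0],
                "maternal_2": [22, 38, 3, 5],
                "paternal_2": [11, 19, 1, 5],
            },
            index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
        )
    )


def make_counts(maternal, paternal, gene_ids=None):
    maternal = np.asarray(maternal)
    if gene_ids is None:
        gene_ids = [f"g{i+1}" for i in range(maternal.shape[0])]
    return AllelicCounts.from_arrays(gene_ids, maternal, paternal)
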