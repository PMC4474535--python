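import numpy as np
import pytest

from xbseq.fixtures import worked_example_counts
from xbseq.model import PairedCounts
from xbseq.simulate import SimulationConfig, assemble_dataset


@pytest.fixture
def worked_example() -> PairedCounts:
    """Four-gene mouse liver example (WT vs MYC, 3 replicates each)."""
    X, B, genes, samples, conditions = worked_example_counts()
    return PairedCounts(genes, samples, conditions, X, B)


@pytest.fixture
def embedded_example() -> PairedCounts:
    """The four-gene example embedded in a simulated 500-gene background so
    size factors and the mean-variance trend are estimable."""
    ds = assemble_dataset(
        SimulationConfig.baseline(
            n_genes=500, n_replicates=3, de_fraction=0.1, fold_change=1.5, seed=7
        )
    )
    X0, B0, genes, samples, conditions = worked_example_counts()
    X = np.vstack([X0, ds.X])
    B = np.vstack([B0, ds.B])
    ids = genes + ds.gene_ids
    return PairedCounts(ids, samples, conditions, X, B)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
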