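import numpy as np
import pytest

from tilelink.pipeline import fit_gene
from tilelink.simulate import SimulationSpec, simulate_multiome


@pytest.fixture(scope="session")
def small_spec():
    # 100-tile windows keep the session fixtures fast
    return SimulationSpec(
        n_cells=600, n_genes=2, gene_length=10_000, flank=20_000, seed=11
    )


@pytest.fixture(scope="session")
def small_ds(small_spec):
    return simulate_multiome(small_spec)


@pytest.fixture(scope="session")
def fitted(small_ds):
    """Fitted results + normalized accessibility for gene_0 of the small dataset."""
    res, X = fit_gene(small_ds, "gene_0", seed=11)
    return res, X


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
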