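import numpy as np
import pandas as pd
import pytest

from coexatlas import AtlasSpec, ExpressionMatrix, PlantedModule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, tie-free."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 5.0, 3.0], [9.0, 7.0, 4.0, 1.0]],
        index=["GA", "GB", "GC"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix("toy", data)


@pytest.fixture
def modular_spec():
    """3 planted modules (50/40/30 genes, loading 0.9) + 200 background."""
    mods = (
        PlantedModule("m1", 50, 0.9, frozenset(["T01"])),
        PlantedModule("m2", 40, 0.9, frozenset(["T01"])),
        PlantedModule("m3", 30, 0.9, frozenset(["T01"])),
    )
    return AtlasSpec(
        n_tissues=1,
        n_genes=320,
        n_samples_per_tissue=100,
        planted_modules=mods,
        seed=7,
    )


def random_symmetric_adjacency(rng, n):
    """Random symmetric matrix with entries in [0, 1] and unit diagonal."""
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a
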