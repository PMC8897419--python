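import numpy as np
import pytest

import domgblup as dg
from domgblup.simulate import preset


def make_genotypes(codes, ids=None, loci=None):
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    ids = ids or [f"i{k}" for k in range(n)]
    loci = loci or [f"L{k}" for k in range(m)]
    return dg.GenotypeMatrix(ids, loci, codes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick additive dataset shared across modules (n=300, m=400)."""
    sc = preset("additive", n_individuals=300, n_loci=400, n_qtl=30)
    return dg.simulate_dataset(sc, seed=42)


@pytest.fixture(scope="session")
def small_corrected(small_dataset):
    return dg.correct_fixed_effects(small_dataset.phenotypes)
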