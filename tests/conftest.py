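import numpy as np
import pytest

from cismr import benchmark as bm
from cismr.genotype_sim import GenotypeMatrix


@pytest.fixture(scope="session")
def small_cache():
    """A small simulated region shared by integration-style tests."""
    return bm.make_region(
        n_variants=250, cohort_sizes=(3000, 1500, 1500), seed=1234
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def make_genotypes(dosages, ids=None, positions=None, a1=None, a2=None):
    """Small helper to build a GenotypeMatrix from a plain dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[1]
    if ids is None:
        ids = [f"v{i}" for i in range(m)]
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=np.array(ids, dtype=object),
        positions=np.array(positions),
        a1=a1,
        a2=a2,
    )
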