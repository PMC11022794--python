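import numpy as np
import pytest

from boostsel.genotype import GenotypeMatrix, PhenotypeTable, VariantSite


def make_matrix(codes, chrom="chr1", sample_prefix="S", positions=None):
    """Build a GenotypeMatrix from a plain nested list of codes."""
    codes = np.asarray(codes, dtype=np.int8)
    n, p = codes.shape
    if positions is None:
        positions = [100 * (j + 1) for j in range(p)]
    sites = [VariantSite(chrom=chrom, pos=pos) for pos in positions]
    ids = [f"{sample_prefix}{i}" for i in range(n)]
    return GenotypeMatrix(sample_ids=ids, sites=sites, codes=codes)


@pytest.fixture
def toy_matrix():
    return make_matrix([
        [0, 1, 2, 0],
        [1, 1, 0, 2],
        [2, 0, 1, -1],
    ])


@pytest.fixture
def toy_phenos():
    return PhenotypeTable(
        assignments={"S0": "a", "S1": "b", "S2": "a"},
        class_set=["a", "b"],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated cohort with strong planted signal, shared across
    model-level tests to amortize training time."""
    from boostsel.simulate import SimulationConfig, simulate_dataset

    config = SimulationConfig(
        n_samples=150, n_sites=400, ld_block_size=5, seed=7,
    )
    return simulate_dataset(config)
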