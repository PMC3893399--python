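import numpy as np
import pytest

from tauroscan.io import GenotypeMatrix
from tauroscan.simulate import SimConfig, simulate_dataset


def make_gm(counts, ploidy=None, chrom="X", positions=None):
    """Small GenotypeMatrix from a plain integer array."""
    counts = np.asarray(counts, dtype=np.int8)
    n, m = counts.shape
    if ploidy is None:
        ploidy = np.ones(n, dtype=np.int8)
    if positions is None:
        positions = 100 * (1 + np.arange(m))
    return GenotypeMatrix(
        animal_ids=[f"an{i}" for i in range(n)],
        marker_ids=[f"snp{j}" for j in range(m)],
        chrom=chrom,
        positions=np.asarray(positions),
        alleles=[("A", "G")] * m,
        counts=counts,
        ploidy=np.asarray(ploidy, dtype=np.int8),
    )


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, n_snps=200, n_animals=120, n_ref_taurus=300,
                     n_ref_indicus=300, tract_interval=(100, 150),
                     candidate_snp_index=125, n_background_snps=200,
                     n_groups=3)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
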