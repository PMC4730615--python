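import numpy as np
import pytest

from twophase_npt import ErrorLaw, group_by_genotype, simulate_genotypes, simulate_trait


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_grouped():
    """Two subjects per genotype group, fully separated."""
    return group_by_genotype([1, 2, 3, 4, 5, 6], [0, 0, 1, 1, 2, 2])


def simulate_null_grouped(n, maf, rng, beta0=0.5):
    """One null cohort grouped by genotype (trait independent of SNP)."""
    g = simulate_genotypes(n, maf, rng)
    y = simulate_trait(g, "NULL", beta0, 0.0, ErrorLaw(), rng)
    return group_by_genotype(y, g)


@pytest.fixture
def null_grouped(rng):
    return simulate_null_grouped(600, 0.3, rng)
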