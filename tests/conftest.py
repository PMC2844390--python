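import numpy as np
import pytest


@pytest.fixture
def balanced_toy():
    """Two populations, two genotype classes, perfectly additive cell means.

    Cell means are 1, 3 (population 0) and 4, 6 (population 1), each cell
    holding two observations at +/-1 around its mean.
    """
    y = np.array([0.0, 2, 2, 4, 3, 5, 5, 7])
    g = np.array([0, 0, 1, 1, 0, 0, 1, 1])
    pop = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    return y, g, pop


@pytest.fixture
def four_cell_toy():
    """Population 0 spans genotypes {0,1}, population 1 spans {1,2}.

    Fitted cell means are 1, 3, 6, 9; the genetic score and baseline
    difference are -2.5 and -3.
    """
    y = np.array([0.0, 2, 2, 4, 5, 7, 8, 10])
    g = np.array([0, 0, 1, 1, 1, 1, 2, 2])
    pop = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    return y, g, pop


def random_cohort_vectors(rng, n_max=30):
    """One random small two-population dataset with an identifiable design."""
    from popeqtl import PopEqtlError, fit_ctwm

    while True:
        n = int(rng.integers(8, n_max + 1))
        pop = rng.integers(0, 2, size=n)
        if len(np.unique(pop)) < 2:
            continue
        maf = rng.uniform(0.15, 0.6)
        g = rng.binomial(2, maf, size=n)
        if len(np.unique(g)) < 2:
            continue
        y = rng.normal(size=n) + g * rng.normal(scale=0.8) + pop * rng.normal(scale=0.8)
        try:
            fit_ctwm(y, g, pop)
        except PopEqtlError:
            continue
        return y, g, pop
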