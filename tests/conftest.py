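import numpy as np
import pytest

from modemdr.data_io import GenotypeMatrix, balanced_cv_split


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_data():
    """Six samples, two SNPs, hand-checkable tallies."""
    genotypes = np.array(
        [[0, 1], [1, 0], [2, 2], [0, 1], [1, 1], [2, 0]]
    )
    phenotype = np.array([1, 1, 1, 0, 0, 0])
    return GenotypeMatrix(genotypes, phenotype, ["A", "B"])


@pytest.fixture
def perfect_data():
    """SNP 0 separates cases and controls perfectly; SNP 1-2 are noise."""
    g = np.random.default_rng(7).integers(0, 3, size=(400, 3))
    phen = np.repeat([1, 0], 200)
    g[:, 0] = phen
    return GenotypeMatrix(g, phen, ["causal", "noise1", "noise2"])


@pytest.fixture
def null_data():
    """Phenotype independent of all genotypes."""
    r = np.random.default_rng(11)
    g = r.integers(0, 3, size=(400, 10))
    phen = np.repeat([1, 0], 200)
    return GenotypeMatrix(g, phen, [f"S{i}" for i in range(10)])


@pytest.fixture
def folds_of(rng):
    def make(data, k=5, seed=5):
        return balanced_cv_split(data, k, np.random.default_rng(seed))

    return make
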