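import numpy as np
import pytest

from genodegrade.model import MISSING, Genotype, GenotypeMatrix, Site


def build_matrix(rows, sample_names=None, ref="A", alt=("T",),
                 phased=False, polarized=False):
    """Build a matrix from a list of per-site genotype lists.

    Each row is a list of (left, right) pairs; None means MISSING.
    """
    n = len(rows[0])
    sample_names = sample_names or [f"s{j + 1}" for j in range(n)]
    sites = []
    for i, row in enumerate(rows):
        gts = [Genotype(MISSING if a is None else a,
                        MISSING if b is None else b, phased)
               for a, b in row]
        sites.append(Site("1", 100 * (i + 1), ".", ref, tuple(alt), gts))
    return GenotypeMatrix.from_sites(sample_names, sites,
                                     polarized=polarized)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng):
    """A 30-site x 8-sample matrix with full, half and no missingness."""
    S, n = 30, 8
    alleles = rng.integers(0, 2, size=(S, n, 2)).astype(np.int16)
    full = rng.random((S, n)) < 0.2
    alleles[full] = MISSING
    half = (rng.random((S, n)) < 0.1) & ~full
    alleles[half, 0] = MISSING
    return GenotypeMatrix(
        [f"s{j}" for j in range(n)], ["1"] * S,
        np.arange(1, S + 1) * 7, ["."] * S, ["A"] * S, [("C",)] * S,
        alleles, np.zeros((S, n), bool))
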