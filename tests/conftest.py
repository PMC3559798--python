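import numpy as np
import pytest

from breeddiv.genotypes import GenotypeMatrix, Locus, Sample


def make_matrix(calls, populations=None, chroms=None, positions=None):
    """Small GenotypeMatrix from a literal call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    populations = populations or ["popA"] * n
    chroms = chroms or ["1"] * L
    positions = positions or [(j + 1) * 1000 for j in range(L)]
    samples = [Sample(f"s{i+1}", populations[i]) for i in range(n)]
    loci = [
        Locus(f"m{j+1}", chroms[j], positions[j], "A", "G") for j in range(L)
    ]
    return GenotypeMatrix(samples, loci, calls)


@pytest.fixture
def toy_matrix():
    # 4 samples, 5 loci, two populations, one missing call
    calls = [
        [0, 1, 2, 0, 1],
        [1, 1, 2, 0, -1],
        [2, 0, 1, 1, 0],
        [2, 0, 1, 2, 0],
    ]
    return make_matrix(calls, populations=["popA", "popA", "popB", "popB"])
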