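import numpy as np
import pytest

from msatpanel import GenotypeMatrix, SimConfig, make_planted_instance, simulate_genotypes


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """Two populations, three loci, hand-written genotypes."""
    calls = np.array(
        [
            [[1, 1], [1, 2], [3, 3]],
            [[1, 2], [2, 2], [3, 4]],
            [[2, 2], [1, 2], [0, 0]],
            [[1, 2], [1, 1], [4, 4]],
        ]
    )
    return GenotypeMatrix(
        individuals=["a", "b", "c", "d"],
        populations=["P1", "P1", "P2", "P2"],
        loci=["mk1", "mk2", "mk3"],
        calls=calls,
    )


@pytest.fixture(scope="session")
def sim_default() -> GenotypeMatrix:
    return simulate_genotypes(SimConfig(seed=11))


@pytest.fixture(scope="session")
def planted():
    """(GenotypeMatrix, planted locus names) with a known optimal panel."""
    return make_planted_instance(k=12, n_best=4, separation=0.85, seed=5)


def random_matrix(rng: np.random.Generator, n: int = 12, k: int = 5) -> GenotypeMatrix:
    """Small random genotype matrix for round-trip testing."""
    calls = rng.integers(1, 9, size=(n, k, 2))
    miss = rng.random((n, k)) < 0.1
    calls[miss] = 0
    pops = rng.choice(["A", "B", "C"], size=n)
    # keep population blocks contiguous, as the GenAlEx layout expects
    pops = np.sort(pops)
    return GenotypeMatrix(
        individuals=[f"i{j}" for j in range(n)],
        populations=list(pops),
        loci=[f"loc{j}" for j in range(k)],
        calls=calls,
    )
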