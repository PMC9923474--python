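import numpy as np
import pytest

from seakernel.genotype_io import GenotypeDataset
from seakernel.synthetic_data import study_count_fixture


@pytest.fixture(scope="session")
def study_fixture():
    """Dataset + site table matching the field study's sampling design."""
    return study_count_fixture(seed=0)


@pytest.fixture
def two_pop_dataset():
    """Tiny hand-written 2-site, 2-locus dataset."""
    return GenotypeDataset(
        loci=["locA", "locB"],
        sites=["s1", "s2"],
        genotypes={
            "s1": [[(1, 2), (5, 5)], [(2, 2), (5, 6)], [(1, 1), (6, 6)]],
            "s2": [[(2, 2), (5, 5)], [(2, 3), (0, 0)]],
        },
    )


def random_dataset(seed: int, n_sites: int = 3, n_loci: int = 4, n_ind: int = 6,
                   missing_rate: float = 0.1) -> GenotypeDataset:
    """Random valid dataset for round-trip and tally property tests."""
    rng = np.random.default_rng(seed)
    sites = [f"p{k}" for k in range(n_sites)]
    genotypes = {}
    for s in sites:
        inds = []
        for _ in range(n_ind):
            row = []
            for _ in range(n_loci):
                if rng.random() < missing_rate:
                    row.append((0, 0))
                else:
                    row.append(tuple(sorted(rng.integers(1, 20, size=2).tolist())))
            inds.append(row)
        genotypes[s] = inds
    return GenotypeDataset(
        loci=[f"L{j}" for j in range(n_loci)], sites=sites, genotypes=genotypes
    )


def wright_fisher_population(n_diploid: int, n_loci: int, generations: int,
                             n_alleles: int, seed: int,
                             monogamy: bool = False) -> GenotypeDataset:
    """Single unstructured Wright-Fisher population, for Nb-recovery checks.

    Independent of the stepping-stone simulator: plain random union of
    gametes from randomly paired parents, no mutation, no structure.
    """
    rng = np.random.default_rng(seed)
    pop = rng.integers(1, n_alleles + 1, size=(n_diploid, n_loci, 2))
    for _ in range(generations):
        if monogamy:
            order = rng.permutation(n_diploid)
            pair_of = np.empty(n_diploid, dtype=int)
            pair_of[order[::2]] = order[1::2]
            pair_of[order[1::2]] = order[::2]
            p1 = rng.integers(0, n_diploid, size=n_diploid)
            p2 = pair_of[p1]
        else:
            p1 = rng.integers(0, n_diploid, size=n_diploid)
            p2 = (p1 + 1 + rng.integers(0, n_diploid - 1, size=n_diploid)) % n_diploid
        child = np.empty_like(pop)
        cols = np.arange(n_loci)[None, :]
        child[:, :, 0] = pop[p1[:, None], cols, rng.integers(0, 2, size=(n_diploid, n_loci))]
        child[:, :, 1] = pop[p2[:, None], cols, rng.integers(0, 2, size=(n_diploid, n_loci))]
        pop = child
    genotypes = {
        "pop": [
            [tuple(sorted(pop[i, j].tolist())) for j in range(n_loci)]
            for i in range(n_diploid)
        ]
    }
    return GenotypeDataset(
        loci=[f"L{j}" for j in range(n_loci)], sites=["pop"], genotypes=genotypes
    )
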