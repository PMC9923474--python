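"""Allele frequencies, heterozygosity, HWP exact test, Weir-Cockerham theta."""

from collections import Counter

import numpy as np
import pytest

from seakernel.genotype_io import GenotypeDataset
from seakernel.popgen_core import (
    allele_frequencies,
    expected_heterozygosity,
    hwe_exact_enumeration,
    hwe_exact_test,
    linearize_fst,
    pairwise_fst,
    wc_theta_pair,
)

from conftest import random_dataset


def single_site(calls, locus="L", site="s"):
    return GenotypeDataset(loci=[locus], sites=[site], genotypes={site: [[g] for g in calls]})


class TestAlleleFrequencies:
    def test_monomorphic(self):
        ds = single_site([(5, 5), (5, 5)])
        t = allele_frequencies(ds, "L", "s")
        assert t.frequencies == {5: 1.0}
        assert t.n_typed == 2

    def test_direct_count(self):
        ds = single_site([(1, 2), (2, 2)])
        t = allele_frequencies(ds, "L", "s")
        assert t.frequencies == {1: 0.25, 2: 0.75}

    def test_missing_excluded(self):
        ds = single_site([(1, 2), (0, 0)])
        t = allele_frequencies(ds, "L", "s")
        assert t.n_typed == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_tally(self, seed):
        ds = random_dataset(seed, n_sites=1, n_loci=1, n_ind=12)
        site, locus = ds.sites[0], ds.loci[0]
        t = allele_frequencies(ds, locus, site)
        tally = Counter()
        for ind in ds.genotypes[site]:
            g = ind[0]
            if g != (0, 0):
                tally[g[0]] += 1
                tally[g[1]] += 1
        assert t.counts == dict(tally)

    def test_all_missing_raises(self):
        ds = single_site([(0, 0), (0, 0)])
        with pytest.raises(ValueError, match="no typed"):
            allele_frequencies(ds, "L", "s")


class TestExpectedHeterozygosity:
    def test_monomorphic_zero(self):
        t = allele_frequencies(single_site([(5, 5)] * 4), "L", "s")
        assert expected_heterozygosity(t, unbiased=False) == 0.0

    def test_two_alleles_half(self):
        t = allele_frequencies(single_site([(1, 2), (1, 2)]), "L", "s")
        assert expected_heterozygosity(t, unbiased=False) == pytest.approx(0.5)

    def test_four_equifrequent(self):
        t = allele_frequencies(single_site([(1, 2), (3, 4)]), "L", "s")
        assert expected_heterozygosity(t, unbiased=False) == pytest.approx(0.75)

    def test_unbiased_exceeds_plain(self):
        t = allele_frequencies(single_site([(1, 2), (2, 2), (1, 1)]), "L", "s")
        assert expected_heterozygosity(t, unbiased=True) > expected_heterozygosity(
            t, unbiased=False
        )

    def test_unbiased_single_individual_undefined(self):
        t = allele_frequencies(single_site([(1, 2)]), "L", "s")
        with pytest.raises(ValueError):
            expected_heterozygosity(t, unbiased=True)


class TestHWEExactTest:
    def test_tiny_table_matches_enumeration(self):
        # allele counts (2, 2): possible tables are {AA, aa} and {Aa, Aa}
        ds = single_site([(1, 1), (2, 2)])
        p_exact = hwe_exact_enumeration({(1, 1): 1, (2, 2): 1})
        assert p_exact == pytest.approx(1.0 / 3.0)
        p_mc = hwe_exact_test(ds, "L", "s", seed=1)
        assert p_mc == pytest.approx(p_exact, abs=0.04)

    def test_het_deficit_matches_enumeration(self):
        calls = [(1, 1)] * 4 + [(2, 2)] * 4
        ds = single_site(calls)
        p_exact = hwe_exact_enumeration(Counter(calls))
        p_mc = hwe_exact_test(ds, "L", "s", seed=2)
        assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_perfect_proportions_not_significant(self):
        calls = [(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25
        ds = single_site(calls)
        assert hwe_exact_test(ds, "L", "s", seed=3) > 0.05

    def test_monomorphic_not_applicable(self):
        ds = single_site([(1, 1)] * 5)
        assert hwe_exact_test(ds, "L", "s", seed=0) is None

    def test_reproducible_per_seed(self):
        calls = [(1, 1)] * 3 + [(1, 2)] * 2 + [(2, 2)] * 5
        ds = single_site(calls)
        kwargs = dict(batches=4, iters_per_batch=500, burn_in=500)
        assert hwe_exact_test(ds, "L", "s", seed=7, **kwargs) == hwe_exact_test(
            ds, "L", "s", seed=7, **kwargs
        )

    def test_enumeration_distribution_sums_to_one(self):
        # the probability-test p-value at the least likely table is that
        # table's own probability; at the most likely table it is 1
        table = {(1, 1): 6, (1, 2): 1, (2, 2): 3}
        p = hwe_exact_enumeration(table)
        assert 0 < p <= 1


def wc_theta_oracle_two_pops(calls_a, calls_b):
    """Independent scalar transcription of the 1984 variance components,
    looped allele by allele (two populations)."""
    alleles = sorted({a for g in calls_a + calls_b for a in g})
    n1, n2 = len(calls_a), len(calls_b)
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    num = den = 0.0
    for al in alleles:
        p1 = sum((g[0] == al) + (g[1] == al) for g in calls_a) / (2 * n1)
        p2 = sum((g[0] == al) + (g[1] == al) for g in calls_b) / (2 * n2)
        h1 = sum((g[0] == al) != (g[1] == al) for g in calls_a) / n1
        h2 = sum((g[0] == al) != (g[1] == al) for g in calls_b) / n2
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestWeirCockerham:
    def test_complete_differentiation(self):
        ds = GenotypeDataset(
            loci=["L"],
            sites=["a", "b"],
            genotypes={"a": [[(1, 1)]] * 3, "b": [[(2, 2)]] * 3},
        )
        assert pairwise_fst(ds).loc("a", "b") == pytest.approx(1.0)

    def test_same_pool_near_zero(self):
        rng = np.random.default_rng(0)
        geno = {
            s: [[tuple(sorted(rng.integers(1, 5, 2).tolist()))] for _ in range(200)]
            for s in ("a", "b")
        }
        ds = GenotypeDataset(loci=["L"], sites=["a", "b"], genotypes=geno)
        assert abs(pairwise_fst(ds).loc("a", "b")) < 0.02

    def test_toy_table_matches_component_oracle(self):
        calls_a = [(1, 1), (1, 2), (2, 2)]
        calls_b = [(2, 2), (2, 2), (1, 2)]
        ds = GenotypeDataset(
            loci=["L"],
            sites=["a", "b"],
            genotypes={"a": [[g] for g in calls_a], "b": [[g] for g in calls_b]},
        )
        theta, _ = wc_theta_pair(ds, "a", "b")
        assert theta == pytest.approx(wc_theta_oracle_two_pops(calls_a, calls_b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_pairs_match_component_oracle(self, seed):
        ds = random_dataset(seed, n_sites=2, n_loci=1, n_ind=8, missing_rate=0.0)
        a, b = ds.sites
        theta, _ = wc_theta_pair(ds, a, b)
        oracle = wc_theta_oracle_two_pops(
            [ind[0] for ind in ds.genotypes[a]], [ind[0] for ind in ds.genotypes[b]]
        )
        assert theta == pytest.approx(oracle, abs=1e-12)

    def test_matrix_symmetric_zero_diagonal(self):
        ds = random_dataset(5, n_sites=4, n_loci=3, n_ind=8)
        fst = pairwise_fst(ds)
        assert np.allclose(fst.values, fst.values.T)
        assert np.all(np.diag(fst.values) == 0)

    def test_invariant_to_site_order_and_allele_relabeling(self):
        ds = random_dataset(6, n_sites=2, n_loci=2, n_ind=8, missing_rate=0.0)
        a, b = ds.sites
        theta_ab, _ = wc_theta_pair(ds, a, b)
        theta_ba, _ = wc_theta_pair(ds, b, a)
        assert theta_ab == pytest.approx(theta_ba, abs=1e-14)
        relabeled = GenotypeDataset(
            loci=ds.loci,
            sites=ds.sites,
            genotypes={
                s: [[(a1 + 100, a2 + 100) for a1, a2 in ind] for ind in ds.genotypes[s]]
                for s in ds.sites
            },
        )
        theta_rel, _ = wc_theta_pair(relabeled, a, b)
        assert theta_rel == pytest.approx(theta_ab, abs=1e-12)

    def test_one_site_rejected(self):
        ds = random_dataset(7, n_sites=1)
        with pytest.raises(ValueError, match="two sites"):
            pairwise_fst(ds)


class TestLinearizeFst:
    @pytest.mark.parametrize(
        "fst,expected",
        [(0.0, 0.0), (0.5, 1.0), (-0.006, -0.006 / 1.006)],
    )
    def test_values(self, fst, expected):
        assert linearize_fst(fst) == pytest.approx(expected)

    def test_monotone(self):
        xs = np.linspace(-0.05, 0.9, 50)
        ys = [linearize_fst(x) for x in xs]
        assert all(b > a for a, b in zip(ys, ys[1:]))

    def test_unity_rejected(self):
        with pytest.raises(ValueError):
            linearize_fst(1.0)
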