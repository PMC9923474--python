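"""Burrows composite LD, the Nb chain, and the density conversion."""

import math

import numpy as np
import pytest

from seakernel.effective_size import (
    LifeHistory,
    RatioEstimate,
    burrows_r2_pair,
    expected_r2_sample,
    invert_r2prime,
    ld_nb,
    linear_effective_density,
    nb_ne_ratio,
    ne_from_nb,
)
from seakernel.genotype_io import GenotypeDataset

from conftest import wright_fisher_population


def burrows_oracle(pairs, allele_a, allele_b):
    """Hand-enumerated Burrows Delta and r for ONE allele pair.

    ``pairs`` is a list of ((a1,a2),(b1,b2)) two-locus genotypes.  Everything
    is computed genotype by genotype with scalar arithmetic, independently of
    the vectorized implementation.
    """
    S = len(pairs)
    xs = [(g1[0] == allele_a) + (g1[1] == allele_a) for g1, _ in pairs]
    ys = [(g2[0] == allele_b) + (g2[1] == allele_b) for _, g2 in pairs]
    p = sum(xs) / (2 * S)
    q = sum(ys) / (2 * S)
    mean_xy = sum(x * y for x, y in zip(xs, ys)) / S
    delta = (S / (S - 1)) * (mean_xy / 2 - 2 * p * q)
    paa = sum(1 for x in xs if x == 2) / S
    qbb = sum(1 for y in ys if y == 2) / S
    da = paa - p * p
    db = qbb - q * q
    r = delta / math.sqrt((p * (1 - p) + da) * (q * (1 - q) + db))
    return delta, r * r


TINY_PAIRS = [
    ((1, 1), (3, 4)),
    ((1, 2), (3, 3)),
    ((2, 2), (4, 4)),
    ((1, 2), (3, 4)),
    ((1, 1), (4, 4)),
    ((2, 2), (3, 4)),
]


class TestBurrowsLD:
    @pytest.mark.parametrize("aa,bb", [(1, 3), (1, 4), (2, 3), (2, 4)])
    def test_tiny_fixture_matches_hand_enumeration(self, aa, bb):
        calls1 = [p[0] for p in TINY_PAIRS]
        calls2 = [p[1] for p in TINY_PAIRS]
        comps = burrows_r2_pair(calls1, calls2, [aa], [bb])
        delta_o, r2_o = burrows_oracle(TINY_PAIRS, aa, bb)
        assert len(comps) == 1
        delta, r2, S = comps[0]
        assert S == 6
        assert delta == pytest.approx(delta_o, abs=1e-14)
        assert r2 == pytest.approx(r2_o, abs=1e-14)

    def test_weighted_mean_equals_hand_aggregate(self):
        calls1 = [p[0] for p in TINY_PAIRS]
        calls2 = [p[1] for p in TINY_PAIRS]
        comps = burrows_r2_pair(calls1, calls2, [1, 2], [3, 4])
        oracle = [burrows_oracle(TINY_PAIRS, a, b)[1] for a in (1, 2) for b in (3, 4)]
        assert np.mean([c[1] for c in comps]) == pytest.approx(np.mean(oracle), abs=1e-14)


class TestSamplingExpectation:
    def test_large_sample_branch(self):
        assert expected_r2_sample(100) == pytest.approx(1 / 100 + 3.19 / 100**2)

    def test_small_sample_branch(self):
        S = 20
        assert expected_r2_sample(S) == pytest.approx(0.0018 + 0.907 / S + 4.44 / S**2)

    def test_inversion_monotone_decreasing(self):
        r2ps = np.linspace(1e-5, 0.02, 30)
        nbs = [invert_r2prime(r, "random") for r in r2ps]
        finite = [n for n in nbs if math.isfinite(n)]
        assert all(b < a for a, b in zip(finite, finite[1:]))

    def test_no_signal_gives_infinite(self):
        assert math.isinf(invert_r2prime(0.0))
        assert math.isinf(invert_r2prime(-1e-4))
        assert math.isinf(invert_r2prime(1.0, "monogamy"))  # negative discriminant


class TestLdNb:
    def test_recovers_known_breeder_number(self):
        """Median LD estimate across replicates within 30% of the true N."""
        true_n = 100
        estimates = []
        for seed in range(20):
            ds = wright_fisher_population(
                n_diploid=true_n, n_loci=16, generations=30, n_alleles=8, seed=seed
            )
            est = ld_nb(ds, pcrit=0.02, mating_model="random")
            estimates.append(est.nb_point)
        median = float(np.median(estimates))
        assert 0.7 * true_n <= median <= 1.3 * true_n

    def test_huge_population_weak_signal(self):
        ds = wright_fisher_population(
            n_diploid=4000, n_loci=2, generations=8, n_alleles=10, seed=5
        )
        sub = GenotypeDataset(
            loci=ds.loci, sites=["pop"], genotypes={"pop": ds.genotypes["pop"][:400]}
        )
        est = ld_nb(sub, pcrit=0.02, mating_model="random")
        assert est.nb_point > 1500 or math.isinf(est.nb_point)

    def test_screening_reduces_comparisons(self):
        ds = wright_fisher_population(
            n_diploid=60, n_loci=6, generations=10, n_alleles=6, seed=2
        )
        loose = ld_nb(ds, pcrit=0.02)
        strict = ld_nb(ds, pcrit=0.15)
        assert strict.n_comparisons <= loose.n_comparisons

    def test_too_few_loci_rejected(self):
        ds = wright_fisher_population(
            n_diploid=20, n_loci=1, generations=2, n_alleles=4, seed=0
        )
        with pytest.raises(ValueError):
            ld_nb(ds)

    def test_pcrit_too_high(self):
        ds = wright_fisher_population(
            n_diploid=20, n_loci=3, generations=2, n_alleles=8, seed=1
        )
        with pytest.raises(ValueError, match="pcrit|usable"):
            ld_nb(ds, pcrit=0.45)

    def test_ci_brackets_point(self):
        ds = wright_fisher_population(
            n_diploid=80, n_loci=10, generations=25, n_alleles=8, seed=3
        )
        est = ld_nb(ds, mating_model="random")
        assert est.ci_low <= est.nb_point <= est.ci_high


class TestLifeHistoryChain:
    def test_study_species_ratio(self):
        r = nb_ne_ratio(LifeHistory(7.05, 1.68))
        assert r.nb_ne_ratio == pytest.approx(0.485 + 0.758 * math.log10(7.05 / 1.68))
        assert r.nb_ne_ratio == pytest.approx(0.957, abs=5e-4)

    def test_ratio_limits(self):
        assert nb_ne_ratio(LifeHistory(3.0, 3.0)).nb_ne_ratio == pytest.approx(0.485)
        assert nb_ne_ratio(LifeHistory(10.0, 1.0)).nb_ne_ratio == pytest.approx(1.243)

    def test_lifespan_below_maturity_rejected(self):
        with pytest.raises(ValueError):
            LifeHistory(1.0, 2.0)

    def test_adjustment_chain_to_ne(self):
        ratio = nb_ne_ratio(LifeHistory(7.05, 1.68))
        nb_adj, ne = ne_from_nb(6942, ratio)
        assert ne == pytest.approx(7625, rel=5e-3)

    def test_unit_denominator_fixed_point(self):
        ratio = RatioEstimate(nb_ne_ratio=0.26 / 0.323)
        nb_adj, _ = ne_from_nb(1234.0, ratio)
        assert nb_adj == pytest.approx(1234.0)

    def test_direct_evaluation_at_unit_ratio(self):
        nb_adj, ne = ne_from_nb(1000.0, RatioEstimate(nb_ne_ratio=1.0))
        assert nb_adj == pytest.approx(1000 / 0.937)
        assert ne == pytest.approx(1000 / 0.937)

    @pytest.mark.parametrize("nb,ratio", [(500.0, 0.7), (6942.0, 0.957), (50.0, 1.2)])
    def test_round_trip_identity(self, nb, ratio):
        _, ne = ne_from_nb(nb, RatioEstimate(nb_ne_ratio=ratio))
        assert ne * ratio * (1.26 - 0.323 * ratio) == pytest.approx(nb, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            ne_from_nb(100.0, RatioEstimate(nb_ne_ratio=4.0))


class TestLinearDensity:
    def test_study_point_value(self):
        d = linear_effective_density(7625.0, 130.0)
        assert d.de == pytest.approx(58.7, abs=0.05)

    def test_unit_case(self):
        assert linear_effective_density(130.0, 130.0).de == pytest.approx(1.0)

    def test_ci_lower_bound_chain(self):
        # propagate the Nb jackknife lower bound through adjustment and division
        ratio = nb_ne_ratio(LifeHistory(7.05, 1.68))
        _, ne_lo = ne_from_nb(779.5, ratio)
        d = linear_effective_density(ne_lo, 130.0)
        assert d.de == pytest.approx(6.6, abs=0.05)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            linear_effective_density(100.0, 0.0)
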