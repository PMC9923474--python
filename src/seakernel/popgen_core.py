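"""Single- and multi-locus genetic statistics.

Implements allele-frequency tallies, expected heterozygosity, the
Guo–Thompson Markov-chain exact test for Hardy–Weinberg proportions, and the
Weir–Cockerham (1984) variance-components estimator of pairwise F_ST with the
ratio-of-sums multilocus combination (the Genepop convention).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset


@dataclass(frozen=True)
class AlleleFrequencyTable:
    locus: str
    site: str
    counts: dict[int, int]  # allele code -> observed allele-copy count
    n_typed: int  # diploid individuals with a non-missing call

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != 2 * self.n_typed:
            raise ValueError("allele-copy count must equal 2 * n_typed")

    @property
    def frequencies(self) -> dict[int, float]:
        tot = 2 * self.n_typed
        return {a: c / tot for a, c in self.counts.items()}


def allele_frequencies(
    dataset: GenotypeDataset, locus: str, site: str
) -> AlleleFrequencyTable:
    """Tally allele copies over non-missing genotypes at one locus and site."""
    calls = [g for g in dataset.site_genotypes(site, locus) if g != (0, 0)]
    if not calls:
        raise ValueError(f"no typed individuals at {locus}/{site}")
    counts: Counter[int] = Counter()
    for a1, a2 in calls:
        counts[a1] += 1
        counts[a2] += 1
    return AlleleFrequencyTable(
        locus=locus, site=site, counts=dict(counts), n_typed=len(calls)
    )


def expected_heterozygosity(
    freqs: AlleleFrequencyTable, unbiased: bool = True
) -> float:
    """Expected heterozygosity ``1 - sum(p^2)``.

    With ``unbiased=True`` applies Nei's small-sample correction
    ``2n/(2n-1) * (1 - sum p^2)`` where n is the number of typed diploids.
    """
    n = freqs.n_typed
    he = 1.0 - sum(p * p for p in freqs.frequencies.values())
    if not unbiased:
        return he
    if n < 2:
        raise ValueError("unbiased He undefined for a single individual")
    return 2 * n / (2 * n - 1) * he


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test (Guo & Thompson 1992 Markov chain)
# ---------------------------------------------------------------------------

NOT_APPLICABLE = None


def _log_table_weight(het: int, cells: dict[tuple[int, int], int]) -> float:
    """log of the part of P(table | allele counts) that varies over tables.

    P(table) ∝ 2^het / prod(n_ij!), the allele-count factorials being fixed.
    """
    return het * math.log(2.0) - sum(math.lgamma(c + 1) for c in cells.values())


def hwe_exact_test(
    dataset: GenotypeDataset,
    locus: str,
    site: str,
    batches: int = 20,
    iters_per_batch: int = 5000,
    burn_in: int = 10000,
    seed: int | None = None,
) -> float | None:
    """Monte-Carlo exact test of Hardy–Weinberg proportions.

    Runs a Guo–Thompson-style switch chain over genotype configurations with
    the observed allele counts held fixed.  Conditioned on allele counts, the
    distribution over labeled-individual configurations is proportional to
    2^het (Levene).  The proposal exchanges one uniformly chosen allele slot
    between two random individuals; its Hastings ratio is 2^(-d_het), which
    cancels the 2^(d_het) target ratio exactly, so every switch is accepted.
    The probability-test p-value is the chain fraction of genotype tables
    whose conditional probability does not exceed that of the observed
    table.  Returns ``None`` (not applicable) for a monomorphic locus.
    """
    calls = [g for g in dataset.site_genotypes(site, locus) if g != (0, 0)]
    if len(calls) < 2:
        raise ValueError("need at least two typed individuals")
    alleles = sorted({a for g in calls for a in g})
    if len(alleles) < 2:
        return NOT_APPLICABLE

    inds = [(min(g), max(g)) for g in calls]
    n = len(inds)
    cells: Counter[tuple[int, int]] = Counter(inds)
    het = sum(1 for a, b in inds if a != b)
    cur_lw = _log_table_weight(het, cells)
    obs_lw = cur_lw

    rng = np.random.default_rng(seed)
    n_steps = burn_in + batches * iters_per_batch
    log2 = math.log(2.0)
    eps = 1e-9
    hits = 0
    total = 0
    # pre-draw the random streams in bulk for speed
    ii = rng.integers(0, n, size=n_steps)
    jj = rng.integers(0, n - 1, size=n_steps)
    which = rng.integers(0, 4, size=n_steps)
    for step in range(n_steps):
        i = ii[step]
        j = jj[step]
        if j >= i:
            j += 1
        g1 = inds[i]
        g2 = inds[j]
        # exchange one uniformly chosen allele slot of i with one of j;
        # the Hastings correction cancels the target ratio, so accept always
        w = which[step]
        a = g1[w & 1]
        keep1 = g1[1 - (w & 1)]
        c = g2[(w >> 1) & 1]
        keep2 = g2[1 - ((w >> 1) & 1)]
        new1 = (min(keep1, c), max(keep1, c))
        new2 = (min(keep2, a), max(keep2, a))
        if not (new1 == g1 and new2 == g2):
            d_het = (
                (new1[0] != new1[1])
                + (new2[0] != new2[1])
                - (g1[0] != g1[1])
                - (g2[0] != g2[1])
            )
            inds[i] = new1
            inds[j] = new2
            for g, delta in ((g1, -1), (g2, -1), (new1, +1), (new2, +1)):
                cur_lw += math.lgamma(cells[g] + 1)
                cells[g] += delta
                cur_lw -= math.lgamma(cells[g] + 1)
            cur_lw += d_het * log2
            het += d_het
        if step >= burn_in:
            total += 1
            if cur_lw <= obs_lw + eps:
                hits += 1
    return hits / total


def hwe_exact_enumeration(genotype_counts: dict[tuple[int, int], int]) -> float:
    """Exact HWP probability-test p-value by full enumeration (2 alleles).

    Independent of the Markov chain; feasible only for tiny two-allele
    tables.  Tables with the same allele counts are parameterised by their
    heterozygote count.
    """
    alleles = sorted({a for g in genotype_counts for a in g})
    if len(alleles) != 2:
        raise ValueError("enumeration oracle supports exactly two alleles")
    x, y = alleles
    n = sum(genotype_counts.values())
    nx = sum(
        c * ((a == x) + (b == x)) for (a, b), c in genotype_counts.items()
    )
    obs_het = genotype_counts.get((x, y), 0) + genotype_counts.get((y, x), 0)

    def log_prob(het: int) -> float:
        nxx = (nx - het) // 2
        nyy = (2 * n - nx - het) // 2
        if nxx < 0 or nyy < 0 or (nx - het) % 2:
            return -math.inf
        # P = n! 2^het / (nxx! het! nyy!) * nx! ny! / (2n)!
        return (
            math.lgamma(n + 1)
            + het * math.log(2.0)
            - math.lgamma(nxx + 1)
            - math.lgamma(het + 1)
            - math.lgamma(nyy + 1)
            + math.lgamma(nx + 1)
            + math.lgamma(2 * n - nx + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = [h for h in range(min(nx, 2 * n - nx) + 1) if log_prob(h) > -math.inf]
    probs = {h: math.exp(log_prob(h)) for h in hets}
    p_obs = probs[obs_het]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


# ---------------------------------------------------------------------------
# Weir–Cockerham (1984) pairwise F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    per_locus: dict[tuple[str, str], dict[str, tuple[float, float]]] | None = None

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def linearized(self) -> "FstMatrix":
        vals = np.vectorize(linearize_fst)(self.values)
        np.fill_diagonal(vals, 0.0)
        return FstMatrix(labels=list(self.labels), values=vals)


def _wc_components_locus(
    calls_by_pop: list[list[tuple[int, int]]],
) -> tuple[float, float, float]:
    """Summed Weir–Cockerham variance components (a, b, c) over alleles.

    ``calls_by_pop`` holds the non-missing genotype calls of each population
    at one locus.  Returns (sum_a, sum_b, sum_c) over all observed alleles;
    a locus monomorphic across the populations yields (0, 0, 0).
    """
    r = len(calls_by_pop)
    n = np.array([len(c) for c in calls_by_pop], dtype=float)
    if np.any(n < 1):
        return 0.0, 0.0, 0.0
    alleles = sorted({a for pop in calls_by_pop for g in pop for a in g})
    if len(alleles) < 2:
        return 0.0, 0.0, 0.0
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    if nc <= 0:
        return 0.0, 0.0, 0.0
    sa = sb = sc = 0.0
    for allele in alleles:
        p = np.array(
            [
                sum((g[0] == allele) + (g[1] == allele) for g in pop) / (2 * len(pop))
                for pop in calls_by_pop
            ]
        )
        h = np.array(
            [
                sum((g[0] == allele) != (g[1] == allele) for g in pop) / len(pop)
                for pop in calls_by_pop
            ]
        )
        pbar = (n * p).sum() / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sa += a
        sb += b
        sc += c
    return sa, sb, sc


def wc_theta_pair(
    dataset: GenotypeDataset, site_a: str, site_b: str
) -> tuple[float, dict[str, tuple[float, float]]]:
    """Multilocus Weir–Cockerham θ for one pair of sites (ratio of sums)."""
    num = 0.0
    den = 0.0
    per_locus: dict[str, tuple[float, float]] = {}
    any_locus = False
    for locus in dataset.loci:
        calls_a = [g for g in dataset.site_genotypes(site_a, locus) if g != (0, 0)]
        calls_b = [g for g in dataset.site_genotypes(site_b, locus) if g != (0, 0)]
        if len(calls_a) < 1 or len(calls_b) < 1:
            continue
        any_locus = True
        a, b, c = _wc_components_locus([calls_a, calls_b])
        per_locus[locus] = (a, a + b + c)
        num += a
        den += a + b + c
    if not any_locus:
        raise ValueError(f"sites {site_a!r}/{site_b!r} share no typed locus")
    if den == 0.0:
        return 0.0, per_locus  # monomorphic across the pair at every locus
    return num / den, per_locus


def pairwise_fst(dataset: GenotypeDataset) -> FstMatrix:
    """Pairwise multilocus Weir–Cockerham θ between all sites."""
    if len(dataset.sites) < 2:
        raise ValueError("pairwise F_ST needs at least two sites")
    k = len(dataset.sites)
    vals = np.zeros((k, k))
    per_locus: dict[tuple[str, str], dict[str, tuple[float, float]]] = {}
    for i in range(k):
        for j in range(i + 1, k):
            theta, comp = wc_theta_pair(dataset, dataset.sites[i], dataset.sites[j])
            vals[i, j] = vals[j, i] = theta
            per_locus[(dataset.sites[i], dataset.sites[j])] = comp
    return FstMatrix(labels=list(dataset.sites), values=vals, per_locus=per_locus)


def linearize_fst(fst: float) -> float:
    """Rousset's linearization F_ST / (1 - F_ST)."""
    if fst >= 1.0:
        raise ValueError("linearized F_ST undefined at F_ST >= 1")
    return fst / (1.0 - fst)
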