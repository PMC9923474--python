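# Methods

## The inference chain

The package estimates the spread σ of a larval dispersal kernel from the
isolation-by-distance (IBD) relation for a one-dimensional habitat: at
drift–migration equilibrium the regression of linearized differentiation
F_ST/(1 − F_ST) on between-site distance has slope m = 1/(4 De σ²), where De
is the linear effective density (effective individuals per km of coastline).
The chain therefore needs three measured quantities — pairwise F_ST, the
slope m, and De — and De is itself derived from a linkage-disequilibrium
estimate of the effective number of breeders.

Assumptions inherited from the theory: roughly constant effective density
along the habitat, dispersal stable for several generations, populations
near drift–migration equilibrium, approximately Wright–Fisher reproduction,
negligible selection at the marker loci, and a habitat whose width is small
compared with the distance between sites. Violations matter in predictable
directions: pooling differentiated sites inflates LD and deflates Nb (a
Wahlund effect), and anomalous long-range connectivity (a current corridor)
flattens the IBD slope and inflates σ.

## Genetic statistics

**Pairwise F_ST** is the Weir–Cockerham (1984) variance-components estimator
θ: for each locus and allele the among-population (a), among-individual (b)
and within-individual (c) components are computed from the two sites'
allele frequencies, heterozygote frequencies and sample sizes; the
multilocus value is Σa / Σ(a+b+c) over alleles and loci (ratio of sums, the
convention of the standard Genepop implementation, which is stable for
weakly polymorphic loci). Negative θ estimates are reported as computed, not
truncated, and loci monomorphic across a pair contribute nothing. Monomorphic
pairs across all loci return θ = 0.

**Hardy–Weinberg exact test.** Conditioned on the allele counts, the
distribution over labeled genotype configurations is proportional to
2^(number of heterozygotes) (Levene's conditional distribution). The sampler
exchanges one uniformly chosen allele slot between two uniformly chosen
individuals; the Hastings ratio of that proposal is 2^(−Δhet), which cancels
the target ratio exactly, so every proposal is accepted and the chain mixes
over configurations while the genotype-table log-weight
(het·log 2 − Σ log n_ij!) is tracked incrementally. The probability-test
p-value is the post-burn-in fraction of visited tables whose conditional
probability does not exceed the observed table's. Defaults follow common
practice: 20 batches × 5000 iterations after 10 000 burn-in steps. A full
enumeration over two-allele tables (`hwe_exact_enumeration`) provides the
exact reference used in tests. Monomorphic loci return a not-applicable
marker rather than raising.

**Mantel machinery.** The Mantel statistic is the Pearson correlation of the
lower-triangle vectors; the null permutes rows and columns of one matrix
simultaneously. When n! − 1 does not exceed the requested permutation count
the test enumerates all relabelings and reports n! − 1 permutations (5039,
719 and 23 for 7, 6 and 4 sites), with p = (count of relabelings with
r ≥ r_obs)/n!; otherwise it samples with a seeded generator and uses the
add-one rule. The default tail is one-sided "greater" (the convention of
vegan, the reference R implementation), so a negative observed correlation
yields p near 1. The partial Mantel uses the first-order partial correlation
and permutes only the first matrix. A pair-resampling bootstrap CI for r is
provided for descriptive use only; it ignores the non-independence of pairs
sharing a site and does not replace the permutation test.

**IBD regression.** Ordinary least squares of linearized F_ST on distance,
one observation per unordered site pair. Pair non-independence is accepted
deliberately — the slope, not its nominal standard error, is the quantity the
theory consumes, and the downstream error propagation treats the reported SE
as a description of slope uncertainty in the same spirit as the original
analyses in this literature.

## Effective size and density

**LD-based Nb.** For every locus pair, individuals typed at both loci form
the comparison sample (pairwise-complete deletion); within it, alleles with
frequency below `pcrit` (default 0.02) are screened out and the most common
remaining allele is dropped as redundant. For each retained allele pair,
Burrows' composite disequilibrium is Δ̂ = S/(S−1)·(mean(X·Y)/2 − 2p̂q̂) with X,
Y the diploid dosages, and r = Δ̂ / √((p(1−p)+D_A)(q(1−q)+D_B)), the D terms
being the within-locus departures from Hardy–Weinberg (P_AA − p²) — the
correction that makes the statistic robust to intra-locus disequilibrium.
The mean r² weights each comparison by its S; the sampling expectation
E[r²_S] (1/S + 3.19/S² for S ≥ 30, else 0.0018 + 0.907/S + 4.44/S²) is
evaluated at the harmonic-mean S and subtracted to give the drift signal
r²′, inverted to N̂b via (1/3 + √(1/9 − 2.76 r²′))/(2r²′) under random mating
or (2/3 + √(4/9 − 7.2 r²′))/(2r²′) under monogamy. Non-positive r²′ or a
negative discriminant yields an infinite estimate (no drift signal). The CI
is a delete-one-locus-pair jackknife on r²′ with normal-theory percentiles;
when the jackknife lower r²′ bound is non-positive the upper Nb bound is
infinite — the expected outcome for large populations, where only the lower
bound is informative.

**Overlapping generations.** Nb/Ne = 0.485 + 0.758·log₁₀(AL/α), the
two-trait life-history regression on adult lifespan and age at maturity,
with the bias adjustment Nb_adj = Nb/(1.26 − 0.323·ratio) and Ne =
Nb_adj/ratio. The ratio's prediction SD defaults to 0.186 and is caller-
overridable. De = Ne / region length. For the study species the chain gives
ratio 0.957, Ne ≈ 7628 and De ≈ 58.7 fish/km from Nb = 6942 over 130 km.
(The ratio printed in the source analysis is 0.958; evaluating the
regression at the printed inputs 7.05 and 1.68 gives 0.9571, so the original
likely used unrounded life-history values. The difference propagates to
< 0.1% in Ne.)

## Error propagation for σ

Each Monte-Carlo draw samples the Nb/Ne ratio from N(ratio, 0.186), the
slope from N(m, SE), and Nb from a chi-squared error distribution fitted to
the jackknife lower bound, then runs the identical deterministic chain
(bias adjustment → Ne → De → σ). Draws with non-positive slope or ratio, or
with a ratio outside the bias adjustment's domain, are rejected and redrawn
(counted; at the study parameters the rejection rate is ≈ 0.06%, driven by
the slope normal). The reported point estimate always comes from the
deterministic inputs; the CI is the 2.5th/97.5th percentile of the draws.

The chi-squared construction deserves care because only "fitted to the lower
confidence bound" is determined by the source description. Two families are
implemented. The default attaches the chi-squared reciprocally,
Nb* = N̂b·df/X with X ~ χ²(df): the LD signal r²′ scales as 1/Nb, so the
precision-like quantity carries the chi-squared error, and the reciprocal
form gives Nb the heavy upper tail consistent with an unbounded upper
confidence limit. Its df is set by quantile-matching the reported lower
bound at the one-sided 5% level (df ≈ 2.9 for 6942/779.5). The direct
scaling Nb* = N̂b·X/df (mean N̂b, 2.5th percentile matched; df ≈ 3.8) is
available via `chi2_form="direct"` and `chi2_fit_level` for sensitivity
analysis. The default was selected because it reproduces the published
downstream results at the study inputs — interval (2.3, 18.1) km against the
published (2.3, 18.4), exceedance fractions 23% and 3.6% against 23% and
3.8% — whereas the direct form yields (4.9, 29.3) and 41%/14%. Exceedance
fractions use ≥; the draws are continuous, so the choice is immaterial.

At 10⁶ draws the CI endpoints are stable to well under 2% across seeds.

## Census density

Linear census density is mean(per-transect areal density) × reef area /
region length. The bootstrap resamples whole transects (the survey is the
exchangeable unit, not the fish) with the BCa construction: bias correction
z₀ from the bootstrap distribution's position relative to the point estimate
(midrank convention at ties), acceleration from the delete-one jackknife
skewness, adjusted percentiles clipped away from 0 and 1 by 1/(n_boot+1).
Defaults: 1000 resamples, 95% level. Constant data collapse the interval to
the point rather than raising. On strongly skewed small samples (lognormal
shape ≥ 0.8, n = 30) BCa undercovers (empirically ≈ 89% for a nominal 95%,
matching the scipy reference implementation exactly); the coverage test
therefore runs at moderate skew, and users with heavily skewed survey data
should treat the interval as approximate.

## Connectivity analyses

Potential-connectivity matrices (directed source→sink transport
probabilities at the end of the pelagic larval duration) are consumed as
inputs. Sampling sites map to the nearest release site by great-circle
distance; sites sharing a release site are flagged for merging before any
genetic comparison (the merge pools individuals and conserves counts). For
Mantel use the directed matrix is reduced to one value per unordered pair —
arithmetic mean of the two directions by default, maximum or raw-forward by
flag; the mean is the least-assumption choice and the flag documents the
ambiguity. The focal-site regression is OLS of linearized F_ST on
connectivity over the pairs containing the focal site. Sign conventions are
reported as computed: higher connectivity correlating with lower genetic
distance appears as negative r.

## The synthetic study system

The stepping-stone simulator emulates the data-generating process IBD theory
assumes. `n_demes` demes sit on a line `deme_spacing` km apart, each with
`deme_size` diploids (De_true = deme_size/spacing); generations do not
overlap; every offspring draws its parent deme from a discretized Gaussian
displacement kernel of spread `sigma_true`, renormalized at the habitat
edges so density stays spatially constant; two distinct parents are drawn
uniformly within the deme (optional monogamous pairing); each transmitted
allele mutates ±1 repeat with probability μ under the stepwise model,
reflecting at the code bounds (which also keeps alleles within 3-digit
Genepop coding). An optional corridor adds migration mass between two demes,
emulating a jet current that shortcuts the distance decay.

Defaults mirror the study conditions the package is tested against: 40 demes
at 5 km (200 km coastline), 250 diploids per deme (De_true = 50/km),
σ_true = 8 km, 16 loci, μ = 5 × 10⁻⁴, 2000 burn-in generations, seven
sampled sites of 20 individuals spanning 150 km. μ = 5 × 10⁻⁴ is a standard
microsatellite per-locus rate and, with these sizes, yields within-site
expected heterozygosities in the 0.5–0.8 range, matching the diversity of
the study's markers. Burn-in of 2000 generations (≈ 8 deme-coalescent units)
is enough for the local IBD pattern, which equilibrates on the migration
timescale, though genome-wide diversity may still drift slowly.

What the simulator does not emulate: overlapping generations (the Waples
adjustment is therefore exercised analytically, and recovery tests use a
unit ratio), genotyping error and allelic dropout, uneven site density,
selection, and real current fields (the synthetic connectivity matrix is a
distance-decay construction with one corridor, not an ocean model). Passing
recovery tests therefore demonstrate the statistical chain, not robustness
to those field complications.

Parameter recovery at the default conditions (ten seeded replicates, run
once): the fitted slope is within a factor of two of 1/(4 De σ²) in the
median, and the full chain — F_ST → slope, pooled LD-Nb over the sampled
span with random-mating inversion and unit ratio → De → σ — lands within a
factor of two of the true 8 km in 8 of 10 replicates; the failures are one
replicate with an extreme Nb estimate and one with an infinite one, the
expected failure mode of LD estimates for thousands of breeders. Pooling
differentiated sites deflates Nb below the true breeder count (Wahlund LD),
which is partly why the method's census-to-effective density ratios run
high in real data as well.

## Numerical and design choices

- Allele coding width for Genepop output defaults to 3 digits (the common
  convention for microsatellite repeat scores); the reader infers 2 vs 3
  from token length.
- Only (0,0) is missing; half-missing calls are rejected as malformed.
- Exhaustive Mantel enumeration auto-engages when n! − 1 ≤ requested
  permutations; `method="sampled"` forces sampling for diagnostics.
- The chi-squared root-find brackets df in [10⁻³, 2^k·10] and returns a
  degenerate point sampler above df = 10⁶ (zero-width limit).
- Expected heterozygosity defaults to the small-sample-corrected (unbiased)
  form; the plain 1 − Σp² is a flag away.
- The outlier site in the pipeline is a configuration entry, not an
  automated detection — identifying it is a scientific judgement the
  original analysis made by inspection, and automating it would overreach.
- Report JSON is schema-versioned; Monte-Carlo draw vectors are not
  serialized (exportable separately as CSV for audit).

## Known limitations

- The jackknife for Nb is over locus pairs; jackknifing over individuals is
  another defensible convention and can give different interval widths.
- The Mantel pair-bootstrap CI is descriptive only.
- With seven sites the IBD slope rests on 21 non-independent pairs; its SE
  is optimistic, which the error propagation inherits.
- LD-based Nb for populations of thousands is lower-bound information in
  practice; σ intervals are correspondingly asymmetric.
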