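# seakernel

Estimating how far coral-reef fish larvae disperse from population-genetic
data. `seakernel` implements the full inference chain from multi-site diploid
microsatellite genotypes to a larval dispersal-kernel spread, for species and
coastlines where the habitat is effectively one-dimensional (a strip of reef
much longer than it is wide). It is aimed at marine population geneticists
and reserve designers who have genotype tables, pairwise distances, and —
optionally — ocean-model connectivity matrices, and want a dispersal estimate
with honest uncertainty.

## The method

In a 1-D habitat at drift–migration equilibrium, genetic differentiation
increases with distance (isolation by distance). Writing F_ST/(1 − F_ST) for
the linearized differentiation between two sites, its regression on distance
has slope

```
m = 1 / (4 De σ²)    ⇒    σ = (4 De m)^(-1/2)
```

where `De` is the linear effective population density (individuals per km of
coast) and `σ` is the standard deviation of the dispersal kernel — the
quantity reserve spacing rules are built on. The package computes each link
of the chain:

- **genotype_io** — Genepop-format reading/writing, site filtering (drop
  sites with fewer than 5 fish), site merging.
- **popgen_core** — allele frequencies, expected heterozygosity, a
  Guo–Thompson Markov-chain exact test of Hardy–Weinberg proportions, and
  pairwise Weir–Cockerham θ combined across loci by the ratio-of-sums rule.
- **spatial_stats** — Mantel and partial Mantel permutation tests (exhaustive
  enumeration when n! − 1 permutations fit the request: 5039 for 7 sites,
  719 for 6, 23 for 4) and the OLS slope `m` with its standard error.
- **effective_size** — the effective number of breeders `Nb` from Burrows
  composite linkage disequilibrium (NeEstimator-style chain: allele screening
  at `P_crit`, sample-size expectation of r², random-mating or monogamy
  inversion, delete-one-locus-pair jackknife CI), the overlapping-generations
  ratio `Nb/Ne = 0.485 + 0.758·log10(AL/α)`, the two-trait bias adjustment
  `Nb_adj = Nb / (1.26 − 0.323·ratio)`, and `De = Ne / L`.
- **dispersal_kernel** — the σ point estimate and a Monte-Carlo error
  propagation: ratio and slope sampled from normals, `Nb` from a chi-squared
  error distribution fitted to the jackknife lower bound, every draw pushed
  through the same deterministic chain; percentile CI and exceedance
  fractions against other species' spreads.
- **density_surveys** — census density from visual transects with a BCa
  bootstrap interval, for the effective-vs-census comparison.
- **oceanography** — potential-connectivity matrices from ocean models:
  nearest-release-site assignment, symmetrization, Mantel/partial-Mantel
  against genetic distance, and a focal-site regression for outlier sites.
- **synthetic_data** — a forward-time 1-D stepping-stone simulator with
  stepwise-mutating microsatellites and known `De` and σ, so the whole chain
  is testable against ground truth without any field data.

## Worked example

The analysis scripts run the chain end to end on a simulated coastline
(40 demes, 5 km apart, 250 diploids each → true `De` = 50 fish/km, true
σ = 8 km, plus one anomalous high-connectivity corridor to the most distant
site):

```
python analysis/01_simulate_fixtures.py
python analysis/02_genetic_structure.py
python analysis/03_effective_density.py
python analysis/04_dispersal_kernel.py
python analysis/05_connectivity.py
```

Step 02 prints, for the seeded default run:

```
Mantel r (all sites):          +0.413  p=0.057 (5039 permutations, exhaustive)
Mantel r (without d33):       +0.601  p=0.008 (719 permutations, exhaustive)
IBD slope: 2.947e-05 ± 1.086e-05 per km (theory for the true parameters: 7.813e-05)
dropping the corridor-connected site strengthens the IBD signal
```

— isolation by distance holds among the ordinary sites but is degraded by the
corridor-connected outlier, and the focal-site regression in step 05
(R² = 0.77, negative slope) shows that site's genetic distances tracking
connectivity rather than geography. Step 04 reproduces the field study's
chain from its published inputs (lifespan 7.05 y, maturity 1.68 y,
Nb = 6942 with lower bound 779.5, slope 5.393 × 10⁻⁵ ± 1.663 × 10⁻⁵ per km,
region length 130 km):

```
  Nb/Ne ratio 0.957; Ne 7628; De 58.7 fish/km
  sigma 8.9 km, 95% MC interval (2.3, 18.1) km
  draws above 11 km: 23%; above 17 km: 3.6%
```

A `seakernel` command-line tool exposes the same steps on your own files
(`seakernel fst`, `ibd`, `nb`, `sigma`, `census`, `connectivity`,
`simulate`, `run-all --config config.yaml`); try
`seakernel sigma --de 58.7 --slope 5.393e-5`, which prints `8.9` (km).

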