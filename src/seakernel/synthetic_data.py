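"""Forward-time 1-D stepping-stone simulator and matched synthetic fixtures.

The simulator produces diploid microsatellite genotypes from a linear chain
of demes with known effective density and Gaussian dispersal spread, so the
whole inference chain (F_ST -> IBD slope -> LD-Nb -> sigma) can be scored
against ground truth without any field data.  Generations do not overlap;
reproduction is Wright-Fisher within demes; each offspring's parent deme is
drawn from a discretized Gaussian displacement kernel renormalized at the
habitat edges (keeping effective density spatially constant, as IBD theory
assumes); microsatellite alleles mutate stepwise (+/-1 repeat) with
reflecting bounds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset, SiteTable, write_genepop
from .spatial_stats import DistanceMatrix

# Sampling design of the field study this package re-analyses: per-site
# sample sizes, island, and IBD-region membership.  Used to build count
# fixtures and realistic synthetic datasets.
STUDY_SITES: list[dict] = [
    {"site_id": "1", "name": "Getafe 1", "island": "Bohol", "n": 20, "ibd": True},
    {"site_id": "2", "name": "Getafe 2", "island": "Bohol", "n": 21, "ibd": True},
    {"site_id": "7", "name": "Santander", "island": "Cebu", "n": 16, "ibd": True},
    {"site_id": "8", "name": "Boljoon", "island": "Cebu", "n": 16, "ibd": True},
    {"site_id": "9", "name": "Argao", "island": "Cebu", "n": 17, "ibd": True},
    {"site_id": "10", "name": "Carcar", "island": "Cebu", "n": 21, "ibd": True},
    {"site_id": "11", "name": "Minglanilla", "island": "Cebu", "n": 19, "ibd": True},
    {"site_id": "13", "name": "Danao", "island": "Cebu", "n": 4, "ibd": False},
    {"site_id": "14", "name": "Sogod", "island": "Cebu", "n": 2, "ibd": False},
    {"site_id": "15", "name": "Tabogon", "island": "Cebu", "n": 1, "ibd": False},
    {"site_id": "19", "name": "Padre Burgos", "island": "Leyte", "n": 20, "ibd": False},
    {"site_id": "22", "name": "Inopacan", "island": "Leyte", "n": 2, "ibd": False},
]

IBD_REGION_SITE_IDS = [s["site_id"] for s in STUDY_SITES if s["ibd"]]


@dataclass(frozen=True)
class SteppingStoneConfig:
    n_demes: int = 40
    deme_spacing: float = 5.0  # km
    deme_size: int = 250  # diploids per deme; D_e_true = deme_size / spacing
    sigma_true: float = 8.0  # km
    n_loci: int = 16
    mutation_rate: float = 5e-4  # per locus per generation, stepwise
    allele_min: int = 100
    allele_max: int = 180
    burn_in: int = 2000  # generations
    sample_sites: tuple[int, ...] = (3, 8, 13, 18, 23, 28, 33)  # deme indices
    sample_n: int = 20
    monogamy: bool = False
    # optional anomalous gene-flow corridor between two demes (indices),
    # emulating a jet current that shortcuts the distance decay
    corridor_demes: tuple[int, int] | None = None
    corridor_strength: float = 0.3  # added migration probability, each direction
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_demes < 2:
            raise ValueError("need at least 2 demes")
        if self.sigma_true <= 0:
            raise ValueError("sigma_true must be positive")
        if not 0 <= self.mutation_rate <= 0.01:
            raise ValueError("mutation_rate must be in [0, 0.01]")
        if any(s < 0 or s >= self.n_demes for s in self.sample_sites):
            raise ValueError("sample sites must be valid deme indices")
        if self.sample_n > self.deme_size:
            raise ValueError("cannot sample more individuals than a deme holds")

    @property
    def de_true(self) -> float:
        return self.deme_size / self.deme_spacing

    @property
    def habitat_length(self) -> float:
        return (self.n_demes - 1) * self.deme_spacing

    def kernel_matrix(self) -> np.ndarray:
        """K[d, s]: probability that an offspring settling in deme d has its
        parents in deme s; Gaussian in |d - s| * spacing, renormalized rows."""
        pos = np.arange(self.n_demes) * self.deme_spacing
        diff = pos[:, None] - pos[None, :]
        k = np.exp(-0.5 * (diff / self.sigma_true) ** 2)
        k = k / k.sum(axis=1, keepdims=True)
        if self.corridor_demes is not None:
            i, j = self.corridor_demes
            k[i, j] += self.corridor_strength
            k[j, i] += self.corridor_strength
            k = k / k.sum(axis=1, keepdims=True)
        return k


def expected_ibd_slope(de: float, sigma: float) -> float:
    """IBD slope m = 1 / (4 De sigma^2) — the inverse of the Rousset relation."""
    if de <= 0 or sigma <= 0:
        raise ValueError("inputs must be positive")
    return 1.0 / (4.0 * de * sigma**2)


def _mutate(alleles: np.ndarray, mu: float, lo: int, hi: int, rng) -> None:
    """Stepwise +/-1 mutation in place, reflecting at the bounds."""
    if mu == 0:
        return
    mask = rng.random(alleles.shape) < mu
    n_mut = int(mask.sum())
    if n_mut == 0:
        return
    step = rng.choice((-1, 1), size=n_mut)
    vals = alleles[mask] + step
    vals[vals < lo] = lo + 1  # reflect
    vals[vals > hi] = hi - 1
    alleles[mask] = vals


def simulate_stepping_stone(
    cfg: SteppingStoneConfig,
) -> tuple[GenotypeDataset, dict]:
    """Run the stepping-stone simulation and sample genotypes.

    Returns a Genepop-writable dataset (one site per sampled deme, sites
    named ``d<index>``) and a truth record with the generating parameters and
    the slope IBD theory predicts for them.
    """
    if cfg.sigma_true > cfg.habitat_length / 2:
        import warnings

        warnings.warn(
            "dispersal spread comparable to habitat length: IBD regime violated",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    n_demes, N, L = cfg.n_demes, cfg.deme_size, cfg.n_loci
    # population state: alleles[deme*N + ind, locus, copy]
    pop = rng.integers(
        cfg.allele_min, cfg.allele_max + 1, size=(n_demes * N, L, 2), dtype=np.int16
    )
    kernel = cfg.kernel_matrix()
    kernel_cdf = np.cumsum(kernel, axis=1)

    for _ in range(cfg.burn_in):
        pop = _next_generation(pop, n_demes, N, L, kernel_cdf, cfg, rng)

    sites = [f"d{d}" for d in cfg.sample_sites]
    genotypes: dict[str, list[list[tuple[int, int]]]] = {}
    for d, sid in zip(cfg.sample_sites, sites):
        idx = rng.choice(N, size=cfg.sample_n, replace=False) + d * N
        genotypes[sid] = [
            [tuple(int(a) for a in pop[i, j]) for j in range(L)] for i in idx
        ]
    dataset = GenotypeDataset(
        loci=[f"loc{j + 1}" for j in range(L)],
        sites=sites,
        genotypes=genotypes,
    )
    truth = {
        "de_true": cfg.de_true,
        "sigma_true": cfg.sigma_true,
        "expected_slope": expected_ibd_slope(cfg.de_true, cfg.sigma_true),
        "deme_spacing": cfg.deme_spacing,
        "sample_sites": list(cfg.sample_sites),
        "positions_km": [d * cfg.deme_spacing for d in cfg.sample_sites],
        "seed": cfg.seed,
    }
    return dataset, truth


def _next_generation(
    pop: np.ndarray,
    n_demes: int,
    N: int,
    L: int,
    kernel_cdf: np.ndarray,
    cfg: SteppingStoneConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One non-overlapping generation, fully vectorized.

    For every offspring slot: draw the parent deme from the kernel, draw two
    distinct parents uniformly within it (or a monogamous pair), transmit one
    random allele per locus from each, then mutate.
    """
    n_off = n_demes * N
    dest = np.repeat(np.arange(n_demes), N)
    u = rng.random(n_off)
    src = (kernel_cdf[dest] < u[:, None]).sum(axis=1)

    if cfg.monogamy:
        # pair individuals within each deme: parent pairs are (2k, 2k+1)
        n_pairs = N // 2
        pair = rng.integers(0, n_pairs, size=n_off)
        p1 = src * N + 2 * pair
        p2 = p1 + 1
    else:
        i1 = rng.integers(0, N, size=n_off)
        i2 = (i1 + 1 + rng.integers(0, N - 1, size=n_off)) % N
        p1 = src * N + i1
        p2 = src * N + i2

    pick1 = rng.integers(0, 2, size=(n_off, L))
    pick2 = rng.integers(0, 2, size=(n_off, L))
    child = np.empty((n_off, L, 2), dtype=pop.dtype)
    rows = np.arange(n_off)[:, None]
    cols = np.arange(L)[None, :]
    child[:, :, 0] = pop[p1[:, None], cols, pick1]
    child[:, :, 1] = pop[p2[:, None], cols, pick2]
    del rows
    _mutate(child, cfg.mutation_rate, cfg.allele_min, cfg.allele_max, rng)
    return child


def geographic_distance_matrix(cfg: SteppingStoneConfig) -> DistanceMatrix:
    """Pairwise distances between sampled demes: spacing * |i - j|."""
    pos = np.array([d * cfg.deme_spacing for d in cfg.sample_sites], dtype=float)
    vals = np.abs(pos[:, None] - pos[None, :])
    return DistanceMatrix(
        labels=[f"d{d}" for d in cfg.sample_sites], values=vals, kind="geographic_km"
    )


def synthetic_connectivity(
    cfg: SteppingStoneConfig,
    decay_km: float = 30.0,
    corridor: tuple[int, int] | None = None,
    corridor_prob: float = 0.3,
) -> np.ndarray:
    """exp(-d / decay) connectivity between sampled demes, with an optional
    anomalous high-connectivity corridor between two site indices (mimicking
    a jet current that shortcuts the distance decay)."""
    pos = np.array([d * cfg.deme_spacing for d in cfg.sample_sites], dtype=float)
    dist = np.abs(pos[:, None] - pos[None, :])
    conn = 0.5 * np.exp(-dist / decay_km)
    if corridor is not None:
        i, j = corridor
        conn[i, j] = conn[j, i] = corridor_prob
    np.fill_diagonal(conn, 0.5)
    return conn


def synthetic_surveys(
    cfg: SteppingStoneConfig,
    mean_density: float = 350.0,  # fish/km²
    cv: float = 0.6,
    seed: int | None = None,
) -> pd.DataFrame:
    """Lognormal per-transect areal densities at the sampled sites."""
    rng = np.random.default_rng(seed)
    s2 = math.log(1 + cv**2)
    mu = math.log(mean_density) - s2 / 2
    rows = []
    for d in cfg.sample_sites:
        area = 0.655 * 0.01  # 655 m transect x two 5 m swaths, km²
        dens = rng.lognormal(mu, math.sqrt(s2))
        rows.append(
            {
                "site_id": f"d{d}",
                "transect_length_m": 655.0,
                "area_km2": area,
                "fish_count": int(round(dens * area)),
            }
        )
    return pd.DataFrame(rows)


def make_fixture_suite(
    cfg: SteppingStoneConfig,
    out_dir: str | Path,
    corridor: tuple[int, int] | str | None = "auto",
) -> dict[str, Path]:
    """Emit a coherent fixture set a full pipeline run can consume.

    Writes a Genepop file, a site-table CSV, a geographic distance CSV, a
    synthetic connectivity CSV (distance decay plus one anomalous corridor),
    a survey CSV and a truth JSON, all derived from one seeded simulation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if corridor == "auto":  # default: first and last sampled site
        corridor = (0, len(cfg.sample_sites) - 1)
    dataset, truth = simulate_stepping_stone(cfg)
    paths = {
        "genepop": out / "genotypes.gen",
        "sites": out / "sites.csv",
        "distances": out / "distances_km.csv",
        "connectivity": out / "connectivity.csv",
        "surveys": out / "surveys.csv",
        "truth": out / "truth.json",
    }
    write_genepop(dataset, paths["genepop"], allele_digits=3)
    site_rows = []
    for k, (d, sid) in enumerate(zip(cfg.sample_sites, dataset.sites)):
        site_rows.append(
            {
                "site_id": sid,
                "name": f"deme {d}",
                "island": "synthetic",
                "longitude": 124.0 + d * cfg.deme_spacing / 111.0,
                "latitude": 10.0,
                "in_ibd_region": True,
            }
        )
    pd.DataFrame(site_rows).to_csv(paths["sites"], index=False)
    geographic_distance_matrix(cfg).to_csv(paths["distances"])
    conn = synthetic_connectivity(cfg, corridor=corridor)
    pd.DataFrame(conn, index=dataset.sites, columns=dataset.sites).to_csv(
        paths["connectivity"]
    )
    synthetic_surveys(cfg, seed=cfg.seed).to_csv(paths["surveys"], index=False)
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


def study_count_fixture(seed: int | None = 0) -> tuple[GenotypeDataset, SiteTable]:
    """A dataset matching the field study's sampling design.

    Per-site sample sizes, names, islands and IBD-region membership follow
    the study's site table; genotypes themselves are synthetic (drawn from a
    common allele pool), so the fixture supports count/filtering/merging
    logic, not allele-level statistics.
    """
    rng = np.random.default_rng(seed)
    loci = [f"loc{j + 1}" for j in range(16)]
    pool = np.arange(120, 140)
    genotypes = {}
    for s in STUDY_SITES:
        inds = []
        for _ in range(s["n"]):
            inds.append(
                [tuple(sorted(rng.choice(pool, 2))) for _ in loci]
            )
        genotypes[s["site_id"]] = [
            [(int(a), int(b)) for a, b in ind] for ind in inds
        ]
    dataset = GenotypeDataset(
        loci=loci, sites=[s["site_id"] for s in STUDY_SITES], genotypes=genotypes
    )
    table = SiteTable(
        pd.DataFrame(
            {
                "site_id": [s["site_id"] for s in STUDY_SITES],
                "name": [s["name"] for s in STUDY_SITES],
                "island": [s["island"] for s in STUDY_SITES],
                "longitude": np.nan,
                "latitude": np.nan,
                "in_ibd_region": [s["ibd"] for s in STUDY_SITES],
            }
        )
    )
    return dataset, table
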