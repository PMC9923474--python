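"""Configuration-driven orchestration of the full analysis chain.

Stages: site filtering -> pairwise F_ST -> Mantel IBD tests (all sites and
excluding a designated outlier site) -> IBD regression -> LD-Nb on the
IBD-region pool -> overlapping-generations adjustment -> linear effective
density -> sigma with Monte-Carlo propagation -> exceedance fractions ->
census density -> connectivity analyses.  Stages whose inputs are absent are
recorded as skipped rather than failing the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .density_surveys import census_density_with_ci, read_surveys
from .dispersal_kernel import PropagationConfig, propagate_sigma
from .effective_size import (
    LifeHistory,
    ld_nb,
    linear_effective_density,
    nb_ne_ratio,
    ne_from_nb,
)
from .genotype_io import GenotypeDataset, SiteTable, read_genepop
from .oceanography import ConnectivityMatrix, connectivity_vs_genetics
from .popgen_core import pairwise_fst
from .spatial_stats import DistanceMatrix, ibd_regression, mantel, partial_mantel

logger = logging.getLogger("seakernel")

REPORT_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    genepop_path: str | None = None
    site_table_path: str | None = None
    distance_csv: str | None = None
    connectivity_csv: str | None = None
    surveys_csv: str | None = None
    min_site_n: int = 5
    ibd_region_sites: list[str] = field(default_factory=list)
    outlier_sites: list[str] = field(default_factory=list)
    merge_sites: list[list[str]] = field(default_factory=list)
    pcrit: float = 0.02
    mating_model: str = "monogamy"
    adult_lifespan: float = 7.05
    age_at_maturity: float = 1.68
    ratio_sd: float = 0.186
    region_length_km: float = 130.0
    reef_area_km2: float = 648.0
    n_draws: int = 1_000_000
    n_permutations: int = 999
    exceedance_thresholds_km: list[float] = field(default_factory=lambda: [11.0, 17.0])
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _jsonable(x: Any) -> Any:
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return {
            k: _jsonable(v)
            for k, v in dataclasses.asdict(x).items()
            if k != "draws"  # bulky Monte-Carlo vectors are not serialized
        }
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, float):
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        if math.isnan(x):
            return None
        return x
    if hasattr(x, "tolist"):
        return _jsonable(x.tolist())
    return x


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_full_analysis(cfg: AnalysisConfig) -> dict[str, Any]:
    """Execute the analysis sequence and return a JSON-serializable report."""
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software_version": __version__,
        "config": _jsonable(cfg.to_dict()),
        "stages": {},
        "skipped": [],
    }
    stages = report["stages"]

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - stage name added for diagnosis
            logger.error("stage %s failed: %s", name, exc)
            raise StageError(name, exc) from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        stages[name] = _jsonable(result)
        return result

    if cfg.genepop_path is None:
        report["skipped"].append("genotypes")
        return report

    dataset = read_genepop(cfg.genepop_path)
    sites: SiteTable | None = None
    if cfg.site_table_path:
        sites = SiteTable.read_csv(cfg.site_table_path)
        if len(sites.site_ids) == len(dataset.sites):
            dataset = GenotypeDataset(
                loci=dataset.loci,
                sites=sites.site_ids,
                genotypes=dict(zip(sites.site_ids, (dataset.genotypes[s] for s in dataset.sites))),
                labels=dict(zip(sites.site_ids, (dataset.labels[s] for s in dataset.sites))),
            )

    dataset = run_stage("filter", lambda: dataset.filter_sites(cfg.min_site_n))
    stages["filter"] = {
        "sites": dataset.sites,
        "site_sizes": dataset.site_sizes(),
        "total_individuals": dataset.n_individuals(),
    }

    fst = run_stage("fst", lambda: pairwise_fst(dataset))
    stages["fst"] = {
        "labels": fst.labels,
        "theta": _jsonable(fst.values),
    }
    linfst = fst.linearized()
    lin_dm = DistanceMatrix(labels=fst.labels, values=linfst.values, kind="linearized_fst")

    geo = None
    if cfg.distance_csv:
        geo = DistanceMatrix.read_csv(cfg.distance_csv, kind="geographic_km").aligned_to(
            fst.labels
        )
        run_stage(
            "mantel_all_sites",
            lambda: mantel(geo, lin_dm, n_perm=cfg.n_permutations, seed=cfg.seed),
        )
        kept = [s for s in fst.labels if s not in cfg.outlier_sites]
        if cfg.outlier_sites and len(kept) >= 4:
            geo_k = geo.aligned_to(kept)
            lin_k = lin_dm.aligned_to(kept)
            run_stage(
                "mantel_excluding_outlier",
                lambda: mantel(geo_k, lin_k, n_perm=cfg.n_permutations, seed=cfg.seed),
            )
            ibd_fit = run_stage("ibd_regression", lambda: ibd_regression(geo_k, lin_k))
        else:
            ibd_fit = run_stage("ibd_regression", lambda: ibd_regression(geo, lin_dm))
    else:
        report["skipped"].append("mantel/ibd_regression")
        ibd_fit = None

    region = [s for s in (cfg.ibd_region_sites or dataset.sites) if s in dataset.sites]
    nb = run_stage(
        "ld_nb",
        lambda: ld_nb(
            dataset.pooled(region, "ibd_region"),
            pcrit=cfg.pcrit,
            mating_model=cfg.mating_model,
        ),
    )
    ratio = run_stage(
        "nb_ne_ratio",
        lambda: nb_ne_ratio(
            LifeHistory(cfg.adult_lifespan, cfg.age_at_maturity), ratio_sd=cfg.ratio_sd
        ),
    )

    if math.isfinite(nb.nb_point):
        _, ne = ne_from_nb(nb.nb_point, ratio)
        ci = None
        if math.isfinite(nb.ci_low):
            _, ne_lo = ne_from_nb(nb.ci_low, ratio)
            ne_hi = ne_from_nb(nb.ci_high, ratio)[1] if math.isfinite(nb.ci_high) else math.inf
            ci = (ne_lo, ne_hi)
        dens = run_stage(
            "effective_density",
            lambda: linear_effective_density(ne, cfg.region_length_km, ci=ci),
        )
        if ibd_fit is not None and ibd_fit.slope > 0 and math.isfinite(nb.ci_low) and nb.ci_low < nb.nb_point:
            def _sigma():
                est = propagate_sigma(
                    PropagationConfig(
                        nb_hat=nb.nb_point,
                        nb_ci_low=nb.ci_low,
                        ratio_mean=ratio.nb_ne_ratio,
                        ratio_sd=ratio.ratio_sd,
                        m_mean=ibd_fit.slope,
                        m_se=ibd_fit.slope_se,
                        region_length=cfg.region_length_km,
                        n_draws=cfg.n_draws,
                        seed=cfg.seed,
                    )
                )
                return {
                    "sigma_point_km": est.sigma_point,
                    "ci_low_km": est.ci_low,
                    "ci_high_km": est.ci_high,
                    "n_draws": est.n_draws,
                    "n_rejected": est.n_rejected,
                    "exceedance_fractions": {
                        str(t): est.exceedance_fraction(t)
                        for t in cfg.exceedance_thresholds_km
                    },
                    "seed": cfg.seed,
                }

            run_stage("sigma", _sigma)
        else:
            report["skipped"].append("sigma")
    else:
        report["skipped"].append("effective_density/sigma (Nb infinite)")

    if cfg.surveys_csv:
        run_stage(
            "census_density",
            lambda: census_density_with_ci(
                read_surveys(cfg.surveys_csv),
                reef_area=cfg.reef_area_km2,
                region_length=cfg.region_length_km,
                seed=cfg.seed,
            ),
        )
    else:
        report["skipped"].append("census_density")

    if cfg.connectivity_csv:
        conn = ConnectivityMatrix.read_csv(cfg.connectivity_csv)
        # sites sharing a release cell are pooled before comparing against
        # connectivity, and F_ST is recomputed on the merged dataset
        conn_dataset = dataset
        for group in cfg.merge_sites:
            present = [s for s in group if s in conn_dataset.sites]
            if len(present) >= 2:
                conn_dataset = conn_dataset.merge_sites(present, "+".join(present))
        if conn_dataset is not dataset:
            conn_fst = run_stage("fst_merged", lambda: pairwise_fst(conn_dataset))
            stages["fst_merged"] = {
                "labels": conn_fst.labels,
                "theta": _jsonable(conn_fst.values),
            }
            conn_lin = DistanceMatrix(
                labels=conn_fst.labels,
                values=conn_fst.linearized().values,
                kind="linearized_fst",
            )
        else:
            conn_fst, conn_lin = fst, lin_dm
        usable = [l for l in conn_fst.labels if l in conn.labels]
        if len(usable) >= 4:
            lin_u = conn_lin.aligned_to(usable)
            run_stage(
                "connectivity_mantel",
                lambda: connectivity_vs_genetics(
                    conn, lin_u, mode="mantel", n_perm=cfg.n_permutations, seed=cfg.seed
                ),
            )
            if geo is not None and all(l in geo.labels for l in usable):
                run_stage(
                    "connectivity_partial_mantel",
                    lambda: connectivity_vs_genetics(
                        conn,
                        lin_u,
                        mode="partial_mantel",
                        control=geo.aligned_to(usable),
                        n_perm=cfg.n_permutations,
                        seed=cfg.seed,
                    ),
                )
            if cfg.outlier_sites and cfg.outlier_sites[0] in usable:
                run_stage(
                    "connectivity_focal_regression",
                    lambda: connectivity_vs_genetics(
                        conn, lin_u, mode="focal_regression",
                        focal_site=cfg.outlier_sites[0],
                    ),
                )
        else:
            report["skipped"].append("connectivity (fewer than 4 shared sites)")
    else:
        report["skipped"].append("connectivity")

    return report


def write_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
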