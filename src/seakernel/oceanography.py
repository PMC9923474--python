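"""Isolation-by-oceanography: potential-connectivity matrices vs genetics.

A potential-connectivity matrix holds the directed probability of passive
larval transport (source row -> sink column) at the end of the pelagic larval
duration, produced externally by Lagrangian particle tracking.  This module
maps genetic sampling sites onto release sites (merging co-located sites),
symmetrizes the matrix for Mantel use, and regresses genetic distance on
connectivity for a focal site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import SiteTable
from .spatial_stats import (
    DistanceMatrix,
    MantelResult,
    RegressionFit,
    mantel,
    ols_fit,
    partial_mantel,
)


@dataclass
class ConnectivityMatrix:
    labels: list[str]
    values: np.ndarray  # directed source->sink probabilities
    pld_days: float | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("connectivity matrix must be square over labels")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("connectivity entries must be probabilities in [0, 1]")

    @classmethod
    def read_csv(
        cls, path: str | Path, pld_days: float | None = None, description: str = ""
    ) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        labels = [str(x) for x in df.index]
        if labels != [str(c) for c in df.columns]:
            raise ValueError("row and column labels differ")
        return cls(
            labels=labels,
            values=df.to_numpy(dtype=float),
            pld_days=pld_days,
            description=description,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    def aligned_to(self, labels: list[str]) -> "ConnectivityMatrix":
        idx = [self.labels.index(l) for l in labels]
        return ConnectivityMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)],
            pld_days=self.pld_days,
            description=self.description,
        )

    def symmetrized(self, how: str = "mean") -> DistanceMatrix:
        """Reduce the directed matrix to one value per unordered pair.

        ``mean`` averages the two directions (least-assumption default),
        ``max`` takes the stronger direction, ``forward`` keeps the matrix as
        is (asymmetric; rejected by Mantel, useful only for export).
        """
        if how == "mean":
            vals = (self.values + self.values.T) / 2.0
        elif how == "max":
            vals = np.maximum(self.values, self.values.T)
        elif how == "forward":
            vals = self.values.copy()
        else:
            raise ValueError("symmetrization must be 'mean', 'max' or 'forward'")
        return DistanceMatrix(
            labels=list(self.labels), values=vals, kind="connectivity_probability"
        )


@dataclass(frozen=True)
class SiteAssignment:
    assignment: dict[str, str]  # sampling site -> release site
    merge_groups: list[list[str]]  # sampling sites sharing a release site


def great_circle_km(
    lon1: float, lat1: float, lon2: float, lat2: float
) -> float:
    """Haversine great-circle distance in km (mean Earth radius 6371 km)."""
    rlat1, rlat2 = math.radians(lat1), math.radians(lat2)
    dlat = rlat2 - rlat1
    dlon = math.radians(lon2 - lon1)
    a = math.sin(dlat / 2) ** 2 + math.cos(rlat1) * math.cos(rlat2) * math.sin(dlon / 2) ** 2
    return 2 * 6371.0 * math.asin(math.sqrt(a))


def assign_release_sites(
    sites: SiteTable, release_coords: pd.DataFrame
) -> SiteAssignment:
    """Nearest release site per sampling site, by great-circle distance.

    ``release_coords`` is indexed by release-site id with ``longitude`` and
    ``latitude`` columns.  Sampling sites mapping to the same release site
    form a merge group (they cannot be distinguished by the connectivity
    matrix and should be pooled before analysis).
    """
    coords = sites.coordinates()
    assignment: dict[str, str] = {}
    for sid, row in coords.iterrows():
        best, best_d = None, math.inf
        for rid, rrow in release_coords.iterrows():
            d = great_circle_km(
                row["longitude"], row["latitude"], rrow["longitude"], rrow["latitude"]
            )
            if d < best_d:
                best, best_d = str(rid), d
        assignment[str(sid)] = best
    groups: dict[str, list[str]] = {}
    for sid, rid in assignment.items():
        groups.setdefault(rid, []).append(sid)
    merge_groups = [g for g in groups.values() if len(g) > 1]
    return SiteAssignment(assignment=assignment, merge_groups=merge_groups)


def connectivity_vs_genetics(
    conn: ConnectivityMatrix,
    linfst: DistanceMatrix,
    mode: str = "mantel",
    focal_site: str | None = None,
    control: DistanceMatrix | None = None,
    symmetrization: str = "mean",
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult | RegressionFit:
    """Test isolation-by-oceanography against linearized F_ST.

    ``mantel`` and ``partial_mantel`` delegate to the permutation machinery
    on the symmetrized connectivity matrix (the partial test controls for
    ``control``, normally geographic distance).  ``focal_regression`` is OLS
    of linearized F_ST on connectivity over the pairs containing
    ``focal_site`` only.
    """
    sym = conn.symmetrized(symmetrization).aligned_to(linfst.labels)
    if mode == "mantel":
        return mantel(sym, linfst, n_perm=n_perm, seed=seed, tail=tail)
    if mode == "partial_mantel":
        if control is None:
            raise ValueError("partial_mantel requires a control matrix")
        return partial_mantel(
            sym, linfst, control.aligned_to(linfst.labels),
            n_perm=n_perm, seed=seed, tail=tail,
        )
    if mode == "focal_regression":
        if focal_site is None or focal_site not in linfst.labels:
            raise ValueError("focal_regression requires a focal site present in labels")
        others = [l for l in linfst.labels if l != focal_site]
        if len(others) < 3:
            raise ValueError("need at least 3 focal pairs")
        x = np.array([sym.loc(focal_site, o) for o in others])
        y = np.array([linfst.loc(focal_site, o) for o in others])
        return ols_fit(x, y)
    raise ValueError("mode must be 'mantel', 'partial_mantel' or 'focal_regression'")
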