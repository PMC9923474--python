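"""Genepop-format I/O and the diploid genotype data model.

Microsatellite genotypes are held as unordered pairs of positive integer
allele codes (repeat scores).  A missing genotype is the pair (0, 0); a
half-missing call (one zero) is rejected because the Genepop format has no
semantics for it.  Sites correspond to Genepop ``pop`` blocks; site ids are
normally supplied by a sidecar site table, with the first individual label
of each block kept as a fallback id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

MISSING = (0, 0)


class GenepopParseError(ValueError):
    """Raised when a Genepop file cannot be parsed."""


@dataclass(frozen=True)
class SiteTable:
    """Per-site metadata: id, name, island, coordinates, IBD-region flag."""

    table: pd.DataFrame

    REQUIRED = ("site_id",)

    def __post_init__(self) -> None:
        if "site_id" not in self.table.columns:
            raise ValueError("site table needs a 'site_id' column")
        ids = self.table["site_id"].astype(str)
        if ids.duplicated().any():
            raise ValueError("duplicate site_id in site table")

    @classmethod
    def read_csv(cls, path: str | Path) -> "SiteTable":
        return cls(pd.read_csv(path, dtype={"site_id": str}))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def site_ids(self) -> list[str]:
        return list(self.table["site_id"].astype(str))

    def ibd_region_sites(self) -> list[str]:
        if "in_ibd_region" not in self.table.columns:
            raise KeyError("site table has no 'in_ibd_region' column")
        mask = self.table["in_ibd_region"].astype(bool)
        return list(self.table.loc[mask, "site_id"].astype(str))

    def coordinates(self) -> pd.DataFrame:
        cols = ["longitude", "latitude"]
        if not all(c in self.table.columns for c in cols):
            raise KeyError("site table lacks longitude/latitude columns")
        out = self.table.set_index(self.table["site_id"].astype(str))[cols]
        if out.isna().any().any():
            raise ValueError("missing coordinates for some sites")
        return out


@dataclass
class GenotypeDataset:
    """Diploid genotypes for individuals grouped by site.

    Attributes
    ----------
    loci : list of str
        Ordered locus names, identical across sites.
    sites : list of str
        Ordered site ids (one per Genepop ``pop`` block).
    genotypes : dict
        site id -> list of individuals; each individual is a list (one entry
        per locus) of ``(a1, a2)`` allele-code pairs, ``(0, 0)`` if missing.
    labels : dict
        site id -> list of individual labels (free text).
    """

    loci: list[str]
    sites: list[str]
    genotypes: dict[str, list[list[tuple[int, int]]]]
    labels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("dataset has zero loci")
        if not self.sites:
            raise ValueError("dataset has zero sites")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate site ids")
        for site in self.sites:
            inds = self.genotypes[site]
            if len(inds) < 1:
                raise ValueError(f"site {site!r} has no individuals")
            for ind in inds:
                if len(ind) != len(self.loci):
                    raise ValueError(
                        f"individual in site {site!r} has {len(ind)} loci, "
                        f"expected {len(self.loci)}"
                    )
                for a1, a2 in ind:
                    validate_call(a1, a2)
            self.labels.setdefault(site, [f"{site}_{i}" for i in range(len(inds))])

    # -- basic accessors ---------------------------------------------------

    def n_individuals(self, site: str | None = None) -> int:
        if site is not None:
            return len(self.genotypes[site])
        return sum(len(v) for v in self.genotypes.values())

    def site_sizes(self) -> dict[str, int]:
        return {s: len(self.genotypes[s]) for s in self.sites}

    def site_genotypes(self, site: str, locus: str) -> list[tuple[int, int]]:
        """All calls (incl. missing) at one locus for one site."""
        j = self.loci.index(locus)
        return [ind[j] for ind in self.genotypes[site]]

    # -- transformations ---------------------------------------------------

    def filter_sites(self, min_n: int) -> "GenotypeDataset":
        """Drop sites with fewer than ``min_n`` individuals."""
        if min_n < 1:
            raise ValueError("min_n must be >= 1")
        keep = [s for s in self.sites if len(self.genotypes[s]) >= min_n]
        if not keep:
            raise ValueError(f"no site has n >= {min_n}")
        return GenotypeDataset(
            loci=list(self.loci),
            sites=keep,
            genotypes={s: [list(i) for i in self.genotypes[s]] for s in keep},
            labels={s: list(self.labels[s]) for s in keep},
        )

    def subset_sites(self, site_ids: Sequence[str]) -> "GenotypeDataset":
        """Keep only the listed sites, in the given order."""
        missing = [s for s in site_ids if s not in self.sites]
        if missing:
            raise KeyError(f"unknown site id(s): {missing}")
        return GenotypeDataset(
            loci=list(self.loci),
            sites=list(site_ids),
            genotypes={s: [list(i) for i in self.genotypes[s]] for s in site_ids},
            labels={s: list(self.labels[s]) for s in site_ids},
        )

    def merge_sites(self, site_ids: Sequence[str], new_id: str) -> "GenotypeDataset":
        """Pool the individuals of several sites into one new site.

        The merged site takes the position of the first listed site; other
        sites are untouched and the total individual count is conserved.
        """
        if len(site_ids) < 2:
            raise ValueError("need at least two sites to merge")
        if len(set(site_ids)) != len(site_ids):
            raise ValueError("duplicate site ids in merge list")
        missing = [s for s in site_ids if s not in self.sites]
        if missing:
            raise KeyError(f"unknown site id(s): {missing}")
        others = [s for s in self.sites if s not in site_ids]
        if new_id in others:
            raise ValueError(f"new site id {new_id!r} collides with an existing site")
        new_sites: list[str] = []
        placed = False
        for s in self.sites:
            if s in site_ids:
                if not placed:
                    new_sites.append(new_id)
                    placed = True
            else:
                new_sites.append(s)
        merged_geno = [list(i) for s in site_ids for i in self.genotypes[s]]
        merged_lab = [lab for s in site_ids for lab in self.labels[s]]
        genotypes = {s: [list(i) for i in self.genotypes[s]] for s in others}
        labels = {s: list(self.labels[s]) for s in others}
        genotypes[new_id] = merged_geno
        labels[new_id] = merged_lab
        return GenotypeDataset(
            loci=list(self.loci), sites=new_sites, genotypes=genotypes, labels=labels
        )

    def pooled(self, site_ids: Sequence[str], pooled_id: str = "pooled") -> "GenotypeDataset":
        """A single-site dataset pooling the listed sites."""
        if len(site_ids) == 1:
            sub = self.subset_sites(site_ids)
            return GenotypeDataset(
                loci=sub.loci,
                sites=[pooled_id],
                genotypes={pooled_id: sub.genotypes[site_ids[0]]},
                labels={pooled_id: sub.labels[site_ids[0]]},
            )
        return self.subset_sites(site_ids).merge_sites(list(site_ids), pooled_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        if self.loci != other.loci or self.sites != other.sites:
            return False
        for s in self.sites:
            a, b = self.genotypes[s], other.genotypes[s]
            if len(a) != len(b):
                return False
            for ia, ib in zip(a, b):
                if [normalize_pair(g) for g in ia] != [normalize_pair(g) for g in ib]:
                    return False
        return True


def normalize_pair(pair: Iterable[int]) -> tuple[int, int]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def validate_call(a1: int, a2: int) -> None:
    if (a1 == 0) != (a2 == 0):
        raise ValueError(f"half-missing genotype ({a1},{a2}) is invalid")
    if a1 < 0 or a2 < 0:
        raise ValueError("allele codes must be non-negative integers")


# ---------------------------------------------------------------------------
# Genepop format
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _infer_digits(tokens: list[str]) -> int:
    """Infer 2- vs 3-digit allele coding from genotype token lengths."""
    lengths = {len(t) for t in tokens if t}
    if lengths <= {4}:
        return 2
    if lengths <= {6}:
        return 3
    raise GenepopParseError(
        f"cannot infer allele coding from token lengths {sorted(lengths)}"
    )


def read_genepop(
    path: str | Path,
    allele_digits: int | str = "auto",
    site_ids: Sequence[str] | None = None,
) -> GenotypeDataset:
    """Read a Genepop file into a :class:`GenotypeDataset`.

    Accepts comma-separated or one-per-line locus headers and case-insensitive
    ``pop`` separators.  ``allele_digits`` may be 2, 3 or ``"auto"`` (inferred
    from token length).  If ``site_ids`` is not given, sites are named after
    the first individual label of each pop block (fallback ``pop_<k>`` when
    labels are blank).
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty file")
    # locus header: everything between the title line and the first "pop"
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        part = lines[i].strip()
        if part:
            loci.extend(x.strip() for x in part.split(",") if x.strip())
        i += 1
    if not loci:
        raise GenepopParseError("no loci declared before first 'pop'")
    if i >= len(lines):
        raise GenepopParseError("no 'pop' blocks found")

    blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        if not raw.strip():
            continue
        if _POP_RE.match(raw):
            current = []
            blocks.append(current)
            continue
        if current is None:
            raise GenepopParseError(f"line {lineno + 1}: data before first 'pop'")
        if "," not in raw:
            raise GenepopParseError(f"line {lineno + 1}: missing ',' after label")
        label, _, rest = raw.partition(",")
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"line {lineno + 1}: {len(tokens)} genotype tokens, "
                f"expected {len(loci)}"
            )
        current.append((label.strip(), tokens))
    if not blocks or any(len(b) == 0 for b in blocks):
        raise GenepopParseError("empty 'pop' block")

    all_tokens = [t for b in blocks for _, toks in b for t in toks]
    if allele_digits == "auto":
        digits = _infer_digits(all_tokens)
    else:
        digits = int(allele_digits)
        if digits not in (2, 3):
            raise ValueError("allele_digits must be 2, 3 or 'auto'")

    if site_ids is not None and len(site_ids) != len(blocks):
        raise GenepopParseError(
            f"{len(site_ids)} site ids supplied for {len(blocks)} pop blocks"
        )

    sites: list[str] = []
    genotypes: dict[str, list[list[tuple[int, int]]]] = {}
    labels: dict[str, list[str]] = {}
    for k, block in enumerate(blocks):
        if site_ids is not None:
            sid = str(site_ids[k])
        else:
            sid = block[0][0] or f"pop_{k + 1}"
        if sid in genotypes:
            sid = f"{sid}_{k + 1}"
        inds = []
        labs = []
        for label, tokens in block:
            row = []
            for t in tokens:
                if len(t) != 2 * digits:
                    raise GenepopParseError(
                        f"token {t!r} has length {len(t)}, expected {2 * digits}"
                    )
                a1, a2 = int(t[:digits]), int(t[digits:])
                try:
                    validate_call(a1, a2)
                except ValueError as exc:
                    raise GenepopParseError(f"token {t!r}: {exc}") from exc
                row.append((a1, a2))
            inds.append(row)
            labs.append(label)
        sites.append(sid)
        genotypes[sid] = inds
        labels[sid] = labs
    return GenotypeDataset(loci=loci, sites=sites, genotypes=genotypes, labels=labels)


def write_genepop(
    dataset: GenotypeDataset,
    path: str | Path,
    allele_digits: int = 3,
    title: str = "seakernel export",
) -> None:
    """Write a dataset in Genepop format (one locus name per line)."""
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    cap = 10**allele_digits
    out = [title]
    out.extend(dataset.loci)
    for site in dataset.sites:
        out.append("pop")
        for label, ind in zip(dataset.labels[site], dataset.genotypes[site]):
            toks = []
            for a1, a2 in ind:
                if a1 >= cap or a2 >= cap:
                    raise ValueError(
                        f"allele code {max(a1, a2)} does not fit in "
                        f"{allele_digits}-digit coding"
                    )
                toks.append(f"{a1:0{allele_digits}d}{a2:0{allele_digits}d}")
            out.append(f"{label} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")
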