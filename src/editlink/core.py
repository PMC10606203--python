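"""Shared domain types: editing sites, read-level haplotype counts, site pairs.

An editing site is a genomic adenosine (on the coding strand) known to
undergo A-to-I editing; reads covering it show A (unedited) or G (edited,
inosine read as guanosine). A pair of editing sites (PES) is two sites
co-covered by at least one read carrying at least one G; the read-level
haplotypes AA / AG / GA / GG (front call, rear call, 5'→3') are the raw
material of the linkage analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "strand"]


@dataclass(frozen=True)
class EditingSite:
    """A known A-to-I editing site (1-based genomic position)."""

    chrom: str
    pos: int
    strand: str
    region: str = "other"  # CDS | UTR | intron | other
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass(frozen=True)
class ReadObservation:
    """Base call of one read at one site, reported on the coding strand."""

    read_id: str
    site: EditingSite
    call: str  # A | G | other


@dataclass
class HaplotypeCounts:
    """Read counts of the four haplotypes for an ordered (front, rear) pair."""

    n_AA: int = 0
    n_AG: int = 0
    n_GA: int = 0
    n_GG: int = 0

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_AG, self.n_GA, self.n_GG) < 0:
            raise ValueError("haplotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_AA + self.n_AG + self.n_GA + self.n_GG

    @property
    def frequencies(self) -> tuple[float, float, float, float]:
        n = self.total
        if n == 0:
            raise ValueError("no co-covering reads: frequencies undefined")
        return (self.n_AA / n, self.n_AG / n, self.n_GA / n, self.n_GG / n)

    def add(self, front_call: str, rear_call: str) -> None:
        setattr(self, f"n_{front_call}{rear_call}",
                getattr(self, f"n_{front_call}{rear_call}") + 1)

    def swapped(self) -> "HaplotypeCounts":
        """Counts with site order reversed (transpose of the 2x2 table)."""
        return HaplotypeCounts(self.n_AA, self.n_GA, self.n_AG, self.n_GG)


@dataclass
class PES:
    """A pair of editing sites: site1 is the front (5') site in transcript
    order, so on minus-strand genes it is the genomically downstream one."""

    site1: EditingSite
    site2: EditingSite
    counts: HaplotypeCounts
    distance: int
    category: str = "other"  # CDS | UTR | intron | other
    distance_kind: str = "genomic"  # spliced | genomic

    @property
    def f_AA(self) -> float:
        return self.counts.frequencies[0]


def load_sites(path: str) -> list[EditingSite]:
    """Read an editing-site table (TSV: chrom, pos, strand[, region, gene_id]).

    Rows are validated, duplicated (chrom, pos, strand) entries dropped with
    a warning, and the result sorted by (chrom, pos).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    sites: list[EditingSite] = []
    seen: set[tuple[str, int, str]] = set()
    n_dup = 0
    for idx, row in df.iterrows():
        try:
            site = EditingSite(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                strand=str(row["strand"]),
                region=str(row["region"]) if "region" in df.columns else "other",
                gene_id=str(row["gene_id"]) if "gene_id" in df.columns else "",
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at line {idx + 2}: {exc}") from exc
        if site.key in seen:
            n_dup += 1
            continue
        seen.add(site.key)
        sites.append(site)
    if n_dup:
        log.warning("%s: dropped %d duplicate site rows", path, n_dup)
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def write_sites(sites: list[EditingSite], path: str, **extra_cols) -> None:
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "strand": [s.strand for s in sites],
            "region": [s.region for s in sites],
            "gene_id": [s.gene_id for s in sites],
            **extra_cols,
        }
    )
    df.to_csv(path, sep="\t", index=False)
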