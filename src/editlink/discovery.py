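"""Pair-of-editing-sites (PES) discovery from aligned reads.

Extraction walks aligned reads (honoring spliced CIGARs), records the base
each read carries at each known editing site on the coding strand, and the
pairing step tallies the AA/AG/GA/GG haplotypes over reads that co-cover two
sites. A pair is kept as a PES only if at least one co-covering read carries
an editing event (f_AA < 1): a pair whose edited reads never span both sites
is unobservable as a pair and is dropped.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import pandas as pd
import pysam

from .core import PES, EditingSite, HaplotypeCounts, ReadObservation
from .models import COMPLEMENT, GeneModels

log = logging.getLogger(__name__)


def extract_observations(
    sam_path: str,
    sites: list[EditingSite],
    min_mapq: int = 0,
    min_baseq: int = 0,
) -> list[ReadObservation]:
    """Per-read base calls at editing sites from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped (counted in
    the log). Calls are complemented for minus-strand sites so they are
    reported on the coding strand; anything other than A/G there becomes
    "other". Sites falling in skipped (N), deleted, or soft-clipped segments
    of a read yield no observation.
    """
    by_chrom: dict[str, dict[int, EditingSite]] = defaultdict(dict)
    for s in sites:
        by_chrom[s.chrom][s.pos - 1] = s  # 0-based keys for pysam

    obs: list[ReadObservation] = []
    n_skipped = 0
    with pysam.AlignmentFile(sam_path, "r") as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                n_skipped += 1
                continue
            if read.mapping_quality < min_mapq:
                n_skipped += 1
                continue
            chrom_sites = by_chrom.get(read.reference_name)
            if not chrom_sites:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                site = chrom_sites.get(rpos)
                if site is None:
                    continue
                if min_baseq and quals is not None and quals[qpos] < min_baseq:
                    continue
                base = seq[qpos].upper()
                if site.strand == "-":
                    base = base.translate(COMPLEMENT)
                call = base if base in ("A", "G") else "other"
                obs.append(ReadObservation(read.query_name, site, call))
    if n_skipped:
        log.info("skipped %d unmapped/secondary/supplementary/low-MAPQ reads",
                 n_skipped)
    return obs


def _transcript_order(s1: EditingSite, s2: EditingSite) -> tuple[EditingSite, EditingSite]:
    """Order two same-strand sites 5'→3' on the coding strand."""
    if (s1.pos < s2.pos) == (s1.strand == "+"):
        return s1, s2
    return s2, s1


def pair_sites(
    observations: list[ReadObservation],
    models: GeneModels | None = None,
) -> list[PES]:
    """Tally haplotypes for every co-observed same-strand site pair.

    For each read, every pair of sites with A/G calls at both positions
    contributes one haplotype; reads with an "other" call at either site are
    excluded from that pair only. Pairs where every co-covering read is AA
    are discarded (not PESs). Distance is spliced-transcript distance when
    both sites are exonic in the same gene (where reading-frame logic is
    defined), genomic otherwise; category requires gene models.
    """
    by_read: dict[str, dict[EditingSite, str]] = defaultdict(dict)
    for o in observations:
        prev = by_read[o.read_id].get(o.site)
        if prev is not None and prev != o.call:
            by_read[o.read_id][o.site] = "other"  # conflicting duplicate call
        else:
            by_read[o.read_id][o.site] = o.call

    tallies: dict[tuple, HaplotypeCounts] = {}
    for calls in by_read.values():
        usable = [(s, c) for s, c in calls.items() if c in ("A", "G")]
        usable.sort(key=lambda sc: (sc[0].chrom, sc[0].pos))
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                (sa, ca), (sb, cb) = usable[i], usable[j]
                if sa.strand != sb.strand or sa.chrom != sb.chrom:
                    continue
                front, rear = _transcript_order(sa, sb)
                fc, rc = (ca, cb) if front is sa else (cb, ca)
                key = (front.key, rear.key)
                if key not in tallies:
                    tallies[key] = HaplotypeCounts()
                tallies[key].add(fc, rc)

    site_by_key = {}
    for o in observations:
        site_by_key[o.site.key] = o.site

    out: list[PES] = []
    for (fkey, rkey), counts in sorted(tallies.items()):
        if counts.total == 0 or counts.n_AA == counts.total:
            continue  # f_AA = 1: no editing event seen on co-covering reads
        front, rear = site_by_key[fkey], site_by_key[rkey]
        distance, kind = pair_distance(front, rear, models)
        pes = PES(front, rear, counts, distance, "other", kind)
        if models is not None:
            pes.category = assign_category(pes, models)
        out.append(pes)
    return out


def pair_distance(
    front: EditingSite, rear: EditingSite, models: GeneModels | None
) -> tuple[int, str]:
    """(distance, kind): spliced-transcript distance for same-gene exonic
    pairs, genomic distance otherwise."""
    if models is not None:
        for t in models.at(front.chrom, front.pos):
            t1 = t.genomic_to_spliced(front.pos)
            t2 = t.genomic_to_spliced(rear.pos)
            if t1 is not None and t2 is not None:
                return abs(t2 - t1), "spliced"
    return abs(rear.pos - front.pos), "genomic"


def assign_category(pes: PES, models: GeneModels) -> str:
    """CDS / UTR / intron when both sites lie in that feature of the same
    gene; anything mixed or unannotated is "other"."""
    for t in models.at(pes.site1.chrom, pes.site1.pos):
        r1 = t.region_of(pes.site1.pos)
        r2 = t.region_of(pes.site2.pos)
        if r1 is not None and r1 == r2:
            return r1
    return "other"


def pes_table(pes_list: list[PES]) -> pd.DataFrame:
    rows = [
        {
            "chrom": p.site1.chrom,
            "pos1": p.site1.pos,
            "pos2": p.site2.pos,
            "strand": p.site1.strand,
            "distance": p.distance,
            "distance_kind": p.distance_kind,
            "category": p.category,
            "n_AA": p.counts.n_AA,
            "n_AG": p.counts.n_AG,
            "n_GA": p.counts.n_GA,
            "n_GG": p.counts.n_GG,
        }
        for p in pes_list
    ]
    return pd.DataFrame(rows)
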