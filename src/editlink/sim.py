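"""Synthetic genomes, editing-site pairs, and pre-aligned reads.

The generator builds a toy chromosome carrying a few multi-exon genes, plants
pairs of adjacent editing sites in CDS (frame types 1-3), UTRs, introns and
intergenic space, and emits spliced SAM alignments whose per-read haplotypes
follow a conditional driver→passenger editing mechanism:

    rear driver:   f_GG = e2·e1_hi      f_AG = e2·(1−e1_hi)
                   f_GA = (1−e2)·e1_lo  f_AA = (1−e2)·(1−e1_lo)

i.e. the rear (driver) site is edited with probability ``e2`` and the front
(passenger) site is edited with probability ``e1_hi`` on driver-edited
molecules but only ``e1_lo`` otherwise. With ``e1_hi > e1_lo`` this yields
the AA→AG→GG trajectory and the f_AG > f_GA haplotype asymmetry that marks a
rear-site driver; the front-driver variant (AA→GA→GG) swaps the roles.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import EditingSite, HaplotypeCounts
from .models import COMPLEMENT, GeneModels, Interval, Transcript

STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]

PAIR_KINDS = ("cds1", "cds2", "cds3", "utr", "intron", "other")

# codon templates: both planted positions must read A on the coding strand
# and carry the frame-dictated Syn/Nonsyn structure of each pair type
_TYPE1_CODON = "AAC"  # pos1: AAC>GAC Asn>Asp (Nonsyn); pos2: AAC>AGC Asn>Ser (Nonsyn)
_TYPE2_CODON = "CAA"  # pos2: CAA>CGA Gln>Arg (Nonsyn); pos3: CAA>CAG Gln>Gln (Syn)
_TYPE3_CODONS = ("GCA", "ACC")  # GCA>GCG Ala (Syn) | ACC>GCC Thr>Ala (Nonsyn)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class GenerationError(RuntimeError):
    """The requested layout does not fit the configured genome."""


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for the synthetic dataset.

    ``e2`` is the driver-site editing level; ``e1_hi``/``e1_lo`` are the
    passenger-site editing probabilities conditional on the driver being
    edited / unedited. Defaults reproduce the adjacent-pair regime seen in
    fly brain data: driver level ~0.7 with strong conditional coupling, so
    type-3 pairs show f_AG > f_GA and a rear-site level around 70%.
    """

    n_genes: int = 2
    exons_per_gene: int = 4
    cds_length: int = 4800
    utr_length: int = 1000
    intron_length: int = 600
    n_pairs_per_type: int = 10
    e2: float = 0.7
    e1_hi: float = 0.9
    e1_lo: float = 0.05
    coverage: int = 200
    read_length: int = 150
    base_error: float = 0.0
    seed: int = 0
    front_driver_type1: bool = True  # type-1 pairs follow AA→GA→GG
    chrom_name: str = "chrS"
    flank: int = 2000

    def __post_init__(self) -> None:
        for name in ("e2", "e1_hi", "e1_lo", "base_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.e1_hi < self.e1_lo:
            raise ConfigError("e1_hi must be >= e1_lo")
        if self.cds_length % 3:
            raise ConfigError(f"cds_length={self.cds_length} not divisible by 3")
        if self.read_length < 1:
            raise ConfigError("read_length must be >= 1")
        if min(self.n_genes, self.exons_per_gene, self.coverage) < 1:
            raise ConfigError("n_genes, exons_per_gene, coverage must be >= 1")


def haplotype_probs(
    e2: float, e1_hi: float, e1_lo: float, driver: str = "rear"
) -> tuple[float, float, float, float]:
    """True (f_AA, f_AG, f_GA, f_GG) of the conditional editing mechanism."""
    if driver == "rear":
        return (
            (1 - e2) * (1 - e1_lo),
            e2 * (1 - e1_hi),
            (1 - e2) * e1_lo,
            e2 * e1_hi,
        )
    if driver == "front":
        return (
            (1 - e2) * (1 - e1_lo),
            (1 - e2) * e1_lo,
            e2 * (1 - e1_hi),
            e2 * e1_hi,
        )
    raise ValueError(f"driver must be 'rear' or 'front', got {driver!r}")


@dataclass(frozen=True)
class SiteTruth:
    site: EditingSite
    level: float  # true per-site editing level
    effect: str  # Nonsyn | Syn | "" (non-CDS)
    cons_class: str  # passenger-Syn | other-Syn | type3-Nonsyn | other-Nonsyn | noncoding


@dataclass(frozen=True)
class PairTruth:
    """Ground truth for one planted pair (front = 5' site on the strand)."""

    pair_id: str
    kind: str  # cds1 | cds2 | cds3 | utr | intron | other
    chrom: str
    strand: str
    gene_id: str
    front: SiteTruth
    rear: SiteTruth
    probs: tuple[float, float, float, float]  # f_AA, f_AG, f_GA, f_GG
    driver: str

    def __post_init__(self) -> None:
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("haplotype probabilities must sum to 1")


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


def _random_cds(rng: np.random.Generator, n_nt: int) -> list[str]:
    n_codons = n_nt // 3
    body = rng.choice(SENSE_CODONS, size=n_codons - 2)
    return list("ATG" + "".join(body) + "TAA")


def generate_genome(config: SimConfig) -> tuple[dict[str, str], GeneModels]:
    """Build the toy chromosome and its gene models.

    Genes alternate strand; each has ``exons_per_gene`` exons with the CDS
    split evenly across them, flanked by UTRs in the terminal exons. The CDS
    always begins ATG, ends with a stop, and contains no internal stop.
    """
    rng = np.random.default_rng(config.seed)
    chrom_parts: list[str] = []
    transcripts: list[Transcript] = []
    offset = 0  # 0-based genomic offset of the next part

    chrom_parts.append("".join(_random_seq(rng, config.flank)))
    offset += config.flank

    n_ex = config.exons_per_gene
    for g in range(config.n_genes):
        strand = "+" if g % 2 == 0 else "-"
        gene_id = f"gene{g + 1}"
        # transcript-ordered per-base labels: utr5 | cds | utr3 | intron
        labels: list[str] = []
        bases: list[str] = []
        cds = _random_cds(rng, config.cds_length)
        chunk = math.ceil(len(cds) / n_ex)
        cds_chunks = [cds[i : i + chunk] for i in range(0, len(cds), chunk)]
        while len(cds_chunks) < n_ex:  # degenerate tiny CDS
            cds_chunks.append([])
        for i in range(n_ex):
            if i == 0:
                bases += _random_seq(rng, config.utr_length)
                labels += ["utr5"] * config.utr_length
            bases += cds_chunks[i]
            labels += ["cds"] * len(cds_chunks[i])
            if i == n_ex - 1:
                bases += _random_seq(rng, config.utr_length)
                labels += ["utr3"] * config.utr_length
            else:
                bases += _random_seq(rng, config.intron_length)
                labels += ["intron"] * config.intron_length
        if strand == "-":
            bases = [b.translate(COMPLEMENT) for b in reversed(bases)]
            labels = labels[::-1]
        chrom_parts.append("".join(bases))
        exons = _runs(labels, offset, lambda lab: lab != "intron")
        cds_ivs = _runs(labels, offset, lambda lab: lab == "cds")
        transcripts.append(
            Transcript(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                chrom=config.chrom_name,
                strand=strand,
                exons=tuple(exons),
                cds=tuple(cds_ivs),
            )
        )
        offset += len(bases)
        chrom_parts.append("".join(_random_seq(rng, config.flank)))
        offset += config.flank

    genome = {config.chrom_name: "".join(chrom_parts)}
    return genome, GeneModels(transcripts)


def _runs(labels: list[str], offset: int, keep) -> list[Interval]:
    ivs = []
    start = None
    for i, lab in enumerate(labels):
        if keep(lab) and start is None:
            start = i
        elif not keep(lab) and start is not None:
            ivs.append(Interval(offset + start + 1, offset + i))
            start = None
    if start is not None:
        ivs.append(Interval(offset + start + 1, offset + len(labels)))
    return ivs


# ---------------------------------------------------------------------------
# pair placement
# ---------------------------------------------------------------------------

def _set_coding_base(chrom: list[str], t: Transcript | None, gpos: int,
                     base: str, strand: str) -> None:
    chrom[gpos - 1] = base if strand == "+" else base.translate(COMPLEMENT)


def place_editing_pairs(
    genome: dict[str, str],
    models: GeneModels,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[PairTruth]]:
    """Plant ``n_pairs_per_type`` adjacent pairs of each kind.

    CDS kinds use fixed codon templates rewritten into the genome so that
    both sites are adenosines on the coding strand and carry the
    frame-dictated Syn/Nonsyn structure; UTR/intron/intergenic pairs are two
    adjacent coding-strand adenosines. Pairs are spaced by more than a read
    length so no read covers sites of two different pairs. Returns the
    edited genome and the ground truth for every pair.
    """
    chrom_name = config.chrom_name
    chrom = list(genome[chrom_name])
    truths: list[PairTruth] = []
    n_per = config.n_pairs_per_type
    spacing_codons = math.ceil(config.read_length / 3) + 2
    transcripts = list(models)

    # ---- CDS pairs -------------------------------------------------------
    per_gene = _split_evenly(n_per, len(transcripts))
    for kind_i, kind in enumerate(("cds1", "cds2", "cds3")):
        counter = 0
        for gi, t in enumerate(transcripts):
            n_here = per_gene[gi]
            n_codons = t.cds_len // 3
            for k in range(n_here):
                # interleave kinds along the CDS: one slot per (kind, k)
                slot = 2 + (k * 3 + kind_i) * spacing_codons
                if slot + 1 >= n_codons - 1:
                    raise GenerationError(
                        f"CDS of {t.gene_id} too short for requested pairs"
                    )
                counter += 1
                truths.append(
                    _place_cds_pair(chrom, t, slot, kind,
                                    f"{kind}_{counter:03d}", config)
                )

    # ---- UTR pairs (3' UTR) ---------------------------------------------
    utr_slots = []
    for t in transcripts:
        t_len = len(t.spliced_genomic_positions)
        utr3_first = t_len - config.utr_length + 1  # transcript coord
        step = config.read_length + 30
        pos = utr3_first + 10
        while pos + 1 <= t_len - 10:
            utr_slots.append((t, pos))
            pos += step
    if len(utr_slots) < n_per:
        raise GenerationError("3' UTRs too short for requested UTR pairs")
    for k in range(n_per):
        t, tpos = utr_slots[k]
        g1, g2 = sorted(
            (t.spliced_to_genomic(tpos), t.spliced_to_genomic(tpos + 1))
        )
        for g in (g1, g2):
            _set_coding_base(chrom, t, g, "A", t.strand)
        truths.append(
            _noncds_truth(f"utr_{k + 1:03d}", "utr", chrom_name, t.strand,
                          t.gene_id, g1, g2, "UTR", config)
        )

    # ---- intron pairs ----------------------------------------------------
    intron_slots = []
    for t in transcripts:
        exons = sorted(t.exons, key=lambda iv: iv.start)
        for a, b in zip(exons, exons[1:]):
            lo, hi = a.end + 1, b.start - 1
            step = config.read_length + 30
            pos = lo + 60
            while pos + 1 <= hi - 60:
                intron_slots.append((t, pos))
                pos += step
    if len(intron_slots) < n_per:
        raise GenerationError("introns too short for requested intron pairs")
    for k in range(n_per):
        t, gpos = intron_slots[k]
        for g in (gpos, gpos + 1):
            _set_coding_base(chrom, t, g, "A", t.strand)
        truths.append(
            _noncds_truth(f"intron_{k + 1:03d}", "intron", chrom_name,
                          t.strand, t.gene_id, gpos, gpos + 1, "intron", config)
        )

    # ---- intergenic ("other") pairs -------------------------------------
    gaps = []
    bound = 1
    for t in transcripts:
        gaps.append((bound, t.start - 1))
        bound = t.end + 1
    gaps.append((bound, len(chrom)))
    other_slots = []
    for lo, hi in gaps:
        step = config.read_length + 50
        pos = lo + 300
        while pos + 1 <= hi - 300:
            other_slots.append(pos)
            pos += step
    if len(other_slots) < n_per:
        raise GenerationError("intergenic space too short for requested pairs")
    for k in range(n_per):
        gpos = other_slots[k]
        chrom[gpos - 1] = "A"
        chrom[gpos] = "A"
        truths.append(
            _noncds_truth(f"other_{k + 1:03d}", "other", chrom_name, "+",
                          "", gpos, gpos + 1, "other", config)
        )

    return {chrom_name: "".join(chrom)}, truths


def _split_evenly(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _place_cds_pair(chrom: list[str], t: Transcript, codon_idx: int,
                    kind: str, pair_id: str, config: SimConfig) -> PairTruth:
    c0 = codon_idx * 3 + 1  # 1-based CDS coord of codon start
    if kind == "cds1":
        codon_edits = {codon_idx: _TYPE1_CODON}
        front_c, rear_c = c0, c0 + 1
        effects = ("Nonsyn", "Nonsyn")
    elif kind == "cds2":
        codon_edits = {codon_idx: _TYPE2_CODON}
        front_c, rear_c = c0 + 1, c0 + 2
        effects = ("Nonsyn", "Syn")
    elif kind == "cds3":
        codon_edits = {codon_idx: _TYPE3_CODONS[0], codon_idx + 1: _TYPE3_CODONS[1]}
        front_c, rear_c = c0 + 2, c0 + 3
        effects = ("Syn", "Nonsyn")
    else:  # pragma: no cover
        raise ValueError(kind)
    for ci, codon in codon_edits.items():
        for j, base in enumerate(codon):
            g = t.cds_to_genomic(ci * 3 + 1 + j)
            _set_coding_base(chrom, t, g, base, t.strand)
    g_front = t.cds_to_genomic(front_c)
    g_rear = t.cds_to_genomic(rear_c)
    driver = "front" if (kind == "cds1" and config.front_driver_type1) else "rear"
    probs = haplotype_probs(config.e2, config.e1_hi, config.e1_lo, driver)
    lv_front = probs[2] + probs[3]  # f_GA + f_GG
    lv_rear = probs[1] + probs[3]  # f_AG + f_GG
    cons = _cons_classes(kind, effects)
    return PairTruth(
        pair_id=pair_id, kind=kind, chrom=t.chrom, strand=t.strand,
        gene_id=t.gene_id,
        front=SiteTruth(
            EditingSite(t.chrom, g_front, t.strand, "CDS", t.gene_id),
            lv_front, effects[0], cons[0]),
        rear=SiteTruth(
            EditingSite(t.chrom, g_rear, t.strand, "CDS", t.gene_id),
            lv_rear, effects[1], cons[1]),
        probs=probs, driver=driver,
    )


def _cons_classes(kind: str, effects: tuple[str, str]) -> tuple[str, str]:
    out = []
    for role, eff in zip(("front", "rear"), effects):
        if eff == "Syn":
            out.append("passenger-Syn" if kind == "cds3" and role == "front"
                       else "other-Syn")
        elif eff == "Nonsyn":
            out.append("type3-Nonsyn" if kind == "cds3" else "other-Nonsyn")
        else:
            out.append("noncoding")
    return tuple(out)  # type: ignore[return-value]


def _noncds_truth(pair_id: str, kind: str, chrom: str, strand: str,
                  gene_id: str, g1: int, g2: int, region: str,
                  config: SimConfig) -> PairTruth:
    # g1 < g2 genomically; on '-' the front (5') site is the higher coordinate
    if strand == "+":
        g_front, g_rear = g1, g2
    else:
        g_front, g_rear = g2, g1
    probs = haplotype_probs(config.e2, config.e1_hi, config.e1_lo, "rear")
    lv_front = probs[2] + probs[3]
    lv_rear = probs[1] + probs[3]
    return PairTruth(
        pair_id=pair_id, kind=kind, chrom=chrom, strand=strand,
        gene_id=gene_id,
        front=SiteTruth(EditingSite(chrom, g_front, strand, region, gene_id),
                        lv_front, "", "noncoding"),
        rear=SiteTruth(EditingSite(chrom, g_rear, strand, region, gene_id),
                       lv_rear, "", "noncoding"),
        probs=probs, driver="rear",
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def simulate_haplotype_counts(
    probs: tuple[float, float, float, float] | PairTruth,
    n_reads: int,
    rng: np.random.Generator,
) -> HaplotypeCounts:
    """Multinomial sample of (AA, AG, GA, GG) read counts from true
    haplotype probabilities."""
    if isinstance(probs, PairTruth):
        probs = probs.probs
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    n_aa, n_ag, n_ga, n_gg = rng.multinomial(n_reads, probs)
    return HaplotypeCounts(int(n_aa), int(n_ag), int(n_ga), int(n_gg))


HAPLOTYPES = ("AA", "AG", "GA", "GG")


def simulate_reads(
    genome: dict[str, str],
    models: GeneModels,
    pairs: list[PairTruth],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[dict], dict[str, HaplotypeCounts]]:
    """Draw per-molecule haplotypes and emit pre-aligned spliced reads.

    Every read of a pair co-covers both its sites; exonic pairs yield
    spliced (N-containing CIGAR) reads in transcript space, intron and
    intergenic pairs yield contiguous genomic reads (pre-mRNA coverage).
    Returns the read records (SAM-ready dicts, coordinate-sorted) and the
    per-pair haplotype tallies actually drawn (after base errors), which a
    lossless extraction must reproduce exactly.

    Base errors flip the edited state at assayed sites (A↔G on the coding
    strand) with probability ``base_error``; other substitution classes are
    invisible to the downstream binary analysis and are not modeled.
    """
    L = config.read_length
    chrom_name = config.chrom_name
    chrom_seq = genome[chrom_name]
    tx_by_gene = {t.gene_id: t for t in models}
    reads: list[dict] = []
    drawn: dict[str, HaplotypeCounts] = {}

    for pair in pairs:
        counts = simulate_haplotype_counts(pair.probs, config.coverage, rng)
        haps: list[str] = []
        for h, n in zip(HAPLOTYPES, (counts.n_AA, counts.n_AG, counts.n_GA,
                                     counts.n_GG)):
            haps.extend([h] * n)
        realized = HaplotypeCounts()
        exonic = pair.kind in ("cds1", "cds2", "cds3", "utr")
        t = tx_by_gene.get(pair.gene_id) if pair.gene_id else None
        if exonic:
            t1 = t.genomic_to_spliced(pair.front.site.pos)
            t2 = t.genomic_to_spliced(pair.rear.site.pos)
            t_len = len(t.spliced_genomic_positions)
            lo = max(1, t2 - L + 1)
            hi = min(t1, t_len - L + 1)
            if hi < lo:
                raise GenerationError(
                    f"read_length {L} cannot co-cover pair {pair.pair_id}")
            starts = rng.integers(lo, hi + 1, size=len(haps))
        else:
            g1 = min(pair.front.site.pos, pair.rear.site.pos)
            g2 = max(pair.front.site.pos, pair.rear.site.pos)
            lo = max(1, g2 - L + 1)
            hi = min(g1, len(chrom_seq) - L + 1)
            if hi < lo:
                raise GenerationError(
                    f"read_length {L} cannot co-cover pair {pair.pair_id}")
            starts = rng.integers(lo, hi + 1, size=len(haps))

        for i, (hap, start) in enumerate(zip(haps, starts)):
            f_edit, r_edit = hap[0] == "G", hap[1] == "G"
            if config.base_error > 0:
                if rng.random() < config.base_error:
                    f_edit = not f_edit
                if rng.random() < config.base_error:
                    r_edit = not r_edit
            realized.add("G" if f_edit else "A", "G" if r_edit else "A")
            edits = {
                pair.front.site.pos: _site_base(f_edit, pair.strand),
                pair.rear.site.pos: _site_base(r_edit, pair.strand),
            }
            if exonic:
                gpos = t.spliced_genomic_positions[start - 1 : start - 1 + L]
                gpos = sorted(gpos)
            else:
                gpos = list(range(int(start), int(start) + L))
            seq = "".join(edits.get(g, chrom_seq[g - 1]) for g in gpos)
            cigar = _blocks_to_cigar(gpos)
            reads.append(
                {
                    "name": f"{pair.pair_id}:{i:05d}",
                    "chrom": chrom_name,
                    "pos": gpos[0],  # 1-based leftmost
                    "cigar": cigar,
                    "seq": seq,
                    "flag": 16 if pair.strand == "-" else 0,
                }
            )
        drawn[pair.pair_id] = realized

    reads.sort(key=lambda r: (r["chrom"], r["pos"], r["name"]))
    return reads, drawn


def _site_base(edited: bool, strand: str) -> str:
    if strand == "+":
        return "G" if edited else "A"
    return "C" if edited else "T"


def _blocks_to_cigar(gpos: list[int]) -> str:
    parts = []
    run_start = gpos[0]
    prev = gpos[0]
    for g in gpos[1:]:
        if g == prev + 1:
            prev = g
            continue
        parts.append(f"{prev - run_start + 1}M{g - prev - 1}N")
        run_start = prev = g
    parts.append(f"{prev - run_start + 1}M")
    return "".join(parts)


def write_sam(reads: list[dict], genome: dict[str, str], path: str) -> None:
    """Write coordinate-sorted single-end alignments as plain SAM."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["name"]
            a.reference_name = r["chrom"]
            a.reference_start = r["pos"] - 1
            a.cigarstring = r["cigar"]
            a.query_sequence = r["seq"]
            a.flag = r["flag"]
            a.mapping_quality = 60
            out.write(a)


# ---------------------------------------------------------------------------
# conservation scores
# ---------------------------------------------------------------------------

DEFAULT_CONS_MEANS = {
    "passenger-Syn": 1.5,
    "other-Syn": 0.0,
    "type3-Nonsyn": 2.0,
    "other-Nonsyn": 2.0,
    "noncoding": 0.0,
}


def simulate_conservation(
    site_classes: list[tuple[EditingSite, str]],
    means_by_class: dict[str, float],
    sd: float,
    rng: np.random.Generator,
):
    """Per-site conservation scores ~ Normal(class mean, sd).

    Emulates per-base phyloP-style scores where passenger synonymous sites
    sit at a higher conservation level than free-standing synonymous sites.
    """
    import pandas as pd

    rows = []
    for site, cls in site_classes:
        if cls not in means_by_class:
            raise ValueError(f"unknown conservation class {cls!r}")
        score = means_by_class[cls] + sd * rng.standard_normal()
        rows.append((site.chrom, site.pos, site.strand, cls, score))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "cons_class", "score"]
    )


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SimDataset:
    """Everything one simulation run produced, in memory."""

    config: SimConfig
    genome: dict[str, str]
    models: GeneModels
    pairs: list[PairTruth]
    reads: list[dict]
    drawn_counts: dict[str, HaplotypeCounts]
    conservation: "object"  # pandas DataFrame

    @property
    def sites(self) -> list[EditingSite]:
        out = []
        for p in self.pairs:
            out.extend([p.front.site, p.rear.site])
        return sorted(out, key=lambda s: (s.chrom, s.pos))


def simulate_dataset(config: SimConfig,
                     cons_sd: float = 1.0,
                     cons_means: dict[str, float] | None = None) -> SimDataset:
    """Run the full generator: genome → pairs → reads → conservation."""
    genome, gene_models = generate_genome(config)
    rng = np.random.default_rng(config.seed + 1)
    genome, pairs = place_editing_pairs(genome, gene_models, config, rng)
    reads, drawn = simulate_reads(genome, gene_models, pairs, config, rng)
    site_classes = []
    for p in pairs:
        site_classes.append((p.front.site, p.front.cons_class))
        site_classes.append((p.rear.site, p.rear.cons_class))
    cons = simulate_conservation(
        site_classes, cons_means or DEFAULT_CONS_MEANS, cons_sd, rng
    )
    return SimDataset(config, genome, gene_models, pairs, reads, drawn, cons)


def write_dataset(ds: SimDataset, outdir: str) -> dict[str, str]:
    """Write FASTA / GFF3 / BED12 / sites TSV / truth TSV / SAM /
    conservation TSV; returns the path of each artifact."""
    import os

    import pandas as pd

    from .models import write_fasta

    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "fasta": "genome.fa", "gff3": "models.gff3", "bed12": "models.bed12",
        "sites": "sites.tsv", "truth": "truth.tsv", "sam": "alignments.sam",
        "conservation": "conservation.tsv",
    }.items()}
    write_fasta(ds.genome, paths["fasta"])
    ds.models.to_gff3(paths["gff3"])
    ds.models.to_bed12(paths["bed12"])
    site_rows = []
    for p in ds.pairs:
        for role, st in (("front", p.front), ("rear", p.rear)):
            site_rows.append(
                (st.site.chrom, st.site.pos, st.site.strand, st.site.region,
                 st.site.gene_id, p.pair_id, role, st.level, st.effect,
                 st.cons_class)
            )
    truth = pd.DataFrame(
        site_rows,
        columns=["chrom", "pos", "strand", "region", "gene_id", "pair_id",
                 "role", "level", "effect", "cons_class"],
    ).sort_values(["chrom", "pos"], kind="mergesort")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    truth[["chrom", "pos", "strand", "region", "gene_id"]].drop_duplicates(
        subset=["chrom", "pos", "strand"]
    ).to_csv(paths["sites"], sep="\t", index=False)
    write_sam(ds.reads, ds.genome, paths["sam"])
    ds.conservation.sort_values(["chrom", "pos"], kind="mergesort").to_csv(
        paths["conservation"], sep="\t", index=False
    )
    return paths
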