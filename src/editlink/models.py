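"""Gene models and coordinate arithmetic.

A :class:`Transcript` holds genomic exon and CDS intervals (1-based,
inclusive) for a single transcript and provides the spliced-coordinate
machinery the rest of the package relies on: mapping a genomic position into
spliced transcript or CDS coordinates (5'→3' on the coding strand) and back.
All distance and reading-frame logic downstream is defined in these spliced
coordinates, because two exonic sites that are adjacent in the mRNA may be
separated by an intron in the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """Closed genomic interval, 1-based."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")

    def __contains__(self, pos: int) -> bool:  # type: ignore[override]
        return self.start <= pos <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    """One transcript of one gene (one transcript per gene in this package).

    ``exons`` and ``cds`` are genomic intervals in ascending genomic order;
    ``strand`` is '+' or '-'. Spliced coordinates run 5'→3' on the coding
    strand, so for minus-strand transcripts they descend genomically.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]
    _g2t: dict[int, int] = field(default_factory=dict, repr=False)
    _g2c: dict[int, int] = field(default_factory=dict, repr=False)
    _t2g: list[int] = field(default_factory=list, repr=False)
    _c2g: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self._t2g = self._spliced_positions(self.exons)
        self._c2g = self._spliced_positions(self.cds)
        self._g2t = {g: i for i, g in enumerate(self._t2g)}
        self._g2c = {g: i for i, g in enumerate(self._c2g)}

    def _spliced_positions(self, ivs: Sequence[Interval]) -> list[int]:
        pos: list[int] = []
        for iv in sorted(ivs, key=lambda i: i.start):
            pos.extend(range(iv.start, iv.end + 1))
        if self.strand == "-":
            pos.reverse()
        return pos

    # -- extents -----------------------------------------------------------
    @property
    def start(self) -> int:
        return min(iv.start for iv in self.exons)

    @property
    def end(self) -> int:
        return max(iv.end for iv in self.exons)

    @property
    def cds_len(self) -> int:
        return len(self._c2g)

    # -- coordinate maps (all 1-based) -------------------------------------
    def genomic_to_spliced(self, pos: int) -> int | None:
        """Spliced transcript coordinate of a genomic position, or None."""
        i = self._g2t.get(pos)
        return None if i is None else i + 1

    def genomic_to_cds(self, pos: int) -> int | None:
        """Spliced CDS coordinate of a genomic position, or None."""
        i = self._g2c.get(pos)
        return None if i is None else i + 1

    def cds_to_genomic(self, cds_pos: int) -> int:
        return self._c2g[cds_pos - 1]

    def spliced_to_genomic(self, t_pos: int) -> int:
        return self._t2g[t_pos - 1]

    @property
    def spliced_genomic_positions(self) -> list[int]:
        """Genomic positions of the spliced transcript in 5'→3' order."""
        return self._t2g

    @property
    def cds_genomic_positions(self) -> list[int]:
        return self._c2g

    # -- sequences ---------------------------------------------------------
    def cds_sequence(self, genome: dict[str, str]) -> str:
        """Spliced CDS on the coding strand."""
        chrom = genome[self.chrom]
        return "".join(
            chrom[g - 1] if self.strand == "+" else chrom[g - 1].translate(COMPLEMENT)
            for g in self._c2g
        ).upper()

    # -- region annotation -------------------------------------------------
    def region_of(self, pos: int) -> str | None:
        """CDS / UTR / intron for a genomic position, or None outside."""
        if any(pos in iv for iv in self.cds):
            return "CDS"
        if any(pos in iv for iv in self.exons):
            return "UTR"
        if self.start <= pos <= self.end:
            return "intron"
        return None


class GeneModels:
    """Collection of transcripts with per-chromosome lookup."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts: list[Transcript] = sorted(
            transcripts, key=lambda t: (t.chrom, t.start)
        )
        self._by_chrom: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    def at(self, chrom: str, pos: int) -> list[Transcript]:
        return [
            t for t in self._by_chrom.get(chrom, []) if t.start <= pos <= t.end
        ]

    def region_of(self, chrom: str, pos: int) -> tuple[str, str | None]:
        """(region, gene_id) of a genomic position.

        CDS wins over UTR wins over intron when transcripts overlap;
        positions in no transcript are 'other'.
        """
        best: tuple[int, str, str | None] = (3, "other", None)
        rank = {"CDS": 0, "UTR": 1, "intron": 2}
        for t in self.at(chrom, pos):
            r = t.region_of(pos)
            if r is not None and rank[r] < best[0]:
                best = (rank[r], r, t.gene_id)
        return best[1], best[2]

    # -- GFF3 / BED12 ------------------------------------------------------
    def to_gff3(self, path: str) -> None:
        lines = ["##gff-version 3"]
        for t in self.transcripts:
            attrs = f"ID={t.gene_id}"
            lines.append(
                "\t".join(
                    [t.chrom, "editlink", "gene", str(t.start), str(t.end), ".",
                     t.strand, ".", attrs]
                )
            )
            lines.append(
                "\t".join(
                    [t.chrom, "editlink", "mRNA", str(t.start), str(t.end), ".",
                     t.strand, ".",
                     f"ID={t.transcript_id};Parent={t.gene_id}"]
                )
            )
            for iv in t.exons:
                lines.append(
                    "\t".join(
                        [t.chrom, "editlink", "exon", str(iv.start), str(iv.end),
                         ".", t.strand, ".", f"Parent={t.transcript_id}"]
                    )
                )
            # phase: bases to skip before the first complete codon
            cds_5to3 = sorted(t.cds, key=lambda i: i.start, reverse=t.strand == "-")
            done = 0
            phased = []
            for iv in cds_5to3:
                phase = (3 - done % 3) % 3
                phased.append((iv, phase))
                done += len(iv)
            for iv, phase in sorted(phased, key=lambda p: p[0].start):
                lines.append(
                    "\t".join(
                        [t.chrom, "editlink", "CDS", str(iv.start), str(iv.end),
                         ".", t.strand, str(phase), f"Parent={t.transcript_id}"]
                    )
                )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def to_bed12(self, path: str) -> None:
        rows = []
        for t in self.transcripts:
            exons = sorted(t.exons, key=lambda i: i.start)
            cds_start = min(iv.start for iv in t.cds) - 1
            cds_end = max(iv.end for iv in t.cds)
            sizes = ",".join(str(len(iv)) for iv in exons)
            starts = ",".join(str(iv.start - 1 - (t.start - 1)) for iv in exons)
            rows.append(
                "\t".join(
                    map(str, [t.chrom, t.start - 1, t.end, t.transcript_id, 0,
                              t.strand, cds_start, cds_end, 0, len(exons),
                              sizes + ",", starts + ","])
                )
            )
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")


def read_gff3(path: str) -> GeneModels:
    """Load gene models from GFF3 (gene/mRNA/exon/CDS) via gffutils."""
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    transcripts = []
    for mrna in db.features_of_type("mRNA"):
        exons = tuple(
            Interval(f.start, f.end)
            for f in db.children(mrna, featuretype="exon", order_by="start")
        )
        cds = tuple(
            Interval(f.start, f.end)
            for f in db.children(mrna, featuretype="CDS", order_by="start")
        )
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        transcripts.append(
            Transcript(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
            )
        )
    return GeneModels(transcripts)


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
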