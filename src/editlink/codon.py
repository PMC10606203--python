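"""Codon context of CDS editing sites and frame classification of pairs.

Editing at codon positions 1 and 2 is nonsynonymous and position 3
synonymous under the positional rule, with one true-effect exception
(ATA→ATG, Ile→Met at position 3) plus the stop-codon edge cases; the
classification of pairs into types 1–4 uses the positional rule, while
site-level Nonsyn/Syn counting elsewhere uses the true codon-table effect.
Distances are spliced-CDS distances, where adjacency and reading frame are
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .core import PES, EditingSite
from .models import GeneModels, Transcript

NONSYN, SYN = "Nonsyn", "Syn"


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())  # '*' for stop


def edit_effect(codon: str, codon_pos: int) -> str:
    """True codon-table effect of an A→G change at ``codon_pos`` (1-3).

    Stop→stop is synonymous; stop→amino-acid (and the reverse) is
    nonsynonymous.
    """
    if codon[codon_pos - 1] != "A":
        raise ValueError(f"codon {codon} has no A at position {codon_pos}")
    edited = codon[: codon_pos - 1] + "G" + codon[codon_pos:]
    return SYN if translate_codon(codon) == translate_codon(edited) else NONSYN


def positional_effect(codon_pos: int) -> str:
    """Frame rule: positions 1-2 nonsynonymous, position 3 synonymous."""
    return SYN if codon_pos == 3 else NONSYN


@dataclass(frozen=True)
class CdsContext:
    site: EditingSite
    transcript: Transcript
    cds_pos: int  # 1-based spliced CDS coordinate
    codon_pos: int  # 1 | 2 | 3
    codon: str  # coding-strand 3-mer
    effect: str  # true codon-table effect
    positional: str  # frame-rule effect


def cds_context(
    site: EditingSite, genome: dict[str, str], models: GeneModels
) -> CdsContext:
    """Codon context of a CDS editing site (strand-resolved).

    Raises if the site is in no annotated CDS or if the coding-strand
    reference base there is not A.
    """
    for t in models.at(site.chrom, site.pos):
        cds_pos = t.genomic_to_cds(site.pos)
        if cds_pos is None:
            continue
        cds_seq = t.cds_sequence(genome)
        base = cds_seq[cds_pos - 1]
        if base != "A":
            raise ValueError(
                f"{site.chrom}:{site.pos}: coding-strand reference base is "
                f"{base}, not A"
            )
        codon_pos = (cds_pos - 1) % 3 + 1
        start = cds_pos - codon_pos
        codon = cds_seq[start : start + 3]
        return CdsContext(
            site=site,
            transcript=t,
            cds_pos=cds_pos,
            codon_pos=codon_pos,
            codon=codon,
            effect=edit_effect(codon, codon_pos),
            positional=positional_effect(codon_pos),
        )
    raise ValueError(f"{site.chrom}:{site.pos} lies in no annotated CDS")


# ---------------------------------------------------------------------------
# pair classification
# ---------------------------------------------------------------------------

TYPE_OF_EFFECTS = {
    (NONSYN, NONSYN): 1,
    (NONSYN, SYN): 2,
    (SYN, NONSYN): 3,
    (SYN, SYN): 4,
}


def distance_group(d: int) -> int:
    """Distance groups: d = 1, 2, 3 → groups 1-3; d = 3n+1, 3n+2, 3n+3
    (n > 0) → groups 4-6."""
    if d < 1:
        raise ValueError(f"distance must be >= 1, got {d}")
    if d <= 3:
        return d
    return 4 + (d - 1) % 3


@dataclass(frozen=True)
class PesClass:
    distance: int  # spliced CDS distance
    group: int  # 1..6
    pes_type: int  # 1..4 from (front, rear) positional effects


def classify_pes(
    pes: PES, ctx_front: CdsContext, ctx_back: CdsContext
) -> PesClass:
    """Distance group and frame type of a CDS pair.

    Both sites must sit in the same transcript; the distance is the spliced
    CDS distance and the type comes from the positional effects of the front
    and rear site.
    """
    if ctx_front.transcript.transcript_id != ctx_back.transcript.transcript_id:
        raise ValueError("PES sites lie in different transcripts")
    d = ctx_back.cds_pos - ctx_front.cds_pos
    if d < 0:  # contexts given in genomic order on a minus-strand gene
        ctx_front, ctx_back = ctx_back, ctx_front
        d = -d
    return PesClass(
        distance=d,
        group=distance_group(d),
        pes_type=TYPE_OF_EFFECTS[(ctx_front.positional, ctx_back.positional)],
    )


def classify_cds_pairs(
    pes_list: list[PES], genome: dict[str, str], models: GeneModels
) -> list[tuple[PES, PesClass]]:
    """Classify every CDS PES; non-CDS pairs are ignored."""
    out = []
    for p in pes_list:
        if p.category != "CDS":
            continue
        c1 = cds_context(p.site1, genome, models)
        c2 = cds_context(p.site2, genome, models)
        out.append((p, classify_pes(p, c1, c2)))
    return out


def group_type_table(classes: list[PesClass]):
    """Counts (and within-group fractions) of pair types by distance group."""
    import pandas as pd

    counts = pd.DataFrame(
        0, index=pd.Index(range(1, 7), name="group"),
        columns=pd.Index(range(1, 5), name="pes_type"),
    )
    for c in classes:
        counts.loc[c.group, c.pes_type] += 1
    totals = counts.sum(axis=1)
    fractions = counts.div(totals.where(totals > 0), axis=0)
    return counts, fractions
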