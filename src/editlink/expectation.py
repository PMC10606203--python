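"""Neutral expectations from the genome sequence.

Two genome-wide null models: (1) the Nonsyn/Syn composition of hypothetical
A→G changes at every (unedited) CDS adenosine, against which the observed
editing-site Nonsyn/Syn ratio is judged; (2) the frame-type composition of
adjacent AA dinucleotides in CDS, against which the observed type mix of
adjacent editing-site pairs is judged. Overlapping AA occurrences all count
(AAA contributes one type-1 and one type-2 pair) since each adjacent
adenosine pair is a potential editing-site pair.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .codon import edit_effect
from .core import EditingSite
from .models import GeneModels, Transcript


@dataclass(frozen=True)
class ExpectationTable:
    n_nonsyn_A: int
    n_syn_A: int
    aa_type_counts: tuple[int, int, int]  # types 1, 2, 3
    scope: str  # "all-genes" | "edited-genes-only"

    @property
    def ratio(self) -> float:
        return self.n_nonsyn_A / self.n_syn_A

    @property
    def aa_type_fractions(self) -> tuple[float, float, float]:
        tot = sum(self.aa_type_counts)
        return tuple(c / tot for c in self.aa_type_counts)  # type: ignore


def _longest_cds_per_gene(models: GeneModels) -> list[Transcript]:
    best: dict[str, Transcript] = {}
    for t in models:
        cur = best.get(t.gene_id)
        if cur is None or t.cds_len > cur.cds_len:
            best[t.gene_id] = t
    return sorted(best.values(), key=lambda t: (t.chrom, t.start))


def expected_nonsyn_syn(
    genome: dict[str, str],
    models: GeneModels,
    scope: str = "all",
    exclude_sites: list[EditingSite] | None = None,
    site_list: list[EditingSite] | None = None,
) -> tuple[int, int]:
    """Count CDS adenosines whose A→G change would be Nonsyn vs Syn.

    Uses the true codon-table effect. One (longest-CDS) transcript per gene
    to avoid double counting. ``exclude_sites`` removes known edited
    positions ("unedited adenosines"); ``scope='edited'`` keeps only genes
    carrying at least one site of ``site_list``. Transcripts whose CDS is
    not a whole number of codons are skipped with a warning.
    """
    import logging

    log = logging.getLogger(__name__)
    excluded = {(s.chrom, s.pos) for s in exclude_sites or []}
    edited_genes = None
    if scope == "edited":
        if site_list is None:
            raise ValueError("scope='edited' requires site_list")
        edited_genes = set()
        for s in site_list:
            for t in models.at(s.chrom, s.pos):
                edited_genes.add(t.gene_id)
    n_nonsyn = n_syn = 0
    for t in _longest_cds_per_gene(models):
        if edited_genes is not None and t.gene_id not in edited_genes:
            continue
        if t.cds_len % 3:
            log.warning("%s: CDS length %d not divisible by 3; skipped",
                        t.transcript_id, t.cds_len)
            continue
        seq = t.cds_sequence(genome)
        gpos = t.cds_genomic_positions
        for i, base in enumerate(seq):
            if base != "A" or (t.chrom, gpos[i]) in excluded:
                continue
            codon_pos = i % 3 + 1
            codon = seq[i - i % 3 : i - i % 3 + 3]
            if edit_effect(codon, codon_pos) == "Nonsyn":
                n_nonsyn += 1
            else:
                n_syn += 1
    return n_nonsyn, n_syn


def expected_aa_types(
    genome: dict[str, str], models: GeneModels
) -> tuple[int, int, int]:
    """Counts of adjacent-AA dinucleotides in spliced CDS by frame type.

    The codon position of the first A decides the type: (1,2)→1, (2,3)→2,
    (3,1 of the next codon)→3. Overlapping occurrences all count.
    """
    counts = [0, 0, 0]
    for t in _longest_cds_per_gene(models):
        seq = t.cds_sequence(genome)
        for i in range(len(seq) - 1):
            if seq[i] == "A" and seq[i + 1] == "A":
                counts[i % 3] += 1
    return tuple(counts)  # type: ignore[return-value]


def expectation_table(
    genome: dict[str, str],
    models: GeneModels,
    scope: str = "all",
    exclude_sites: list[EditingSite] | None = None,
    site_list: list[EditingSite] | None = None,
) -> ExpectationTable:
    n_nonsyn, n_syn = expected_nonsyn_syn(
        genome, models, scope, exclude_sites, site_list
    )
    return ExpectationTable(
        n_nonsyn_A=n_nonsyn,
        n_syn_A=n_syn,
        aa_type_counts=expected_aa_types(genome, models),
        scope="edited-genes-only" if scope == "edited" else "all-genes",
    )


def chi_square_gof(
    observed: tuple[int, ...] | list[int],
    expected_counts: tuple[int, ...] | list[int],
) -> tuple[float, float]:
    """Pearson goodness-of-fit of observed counts against the proportions of
    (typically much larger) expected counts, k−1 df."""
    if len(observed) != len(expected_counts):
        raise ValueError("observed and expected must cover the same categories")
    total_obs = sum(observed)
    total_exp = sum(expected_counts)
    if total_exp == 0:
        raise ValueError("expected counts sum to zero")
    f_exp = []
    for o, e in zip(observed, expected_counts):
        if e == 0 and o > 0:
            raise ValueError("expected count 0 in a category with nonzero "
                             "observed count")
        f_exp.append(e / total_exp * total_obs)
    res = stats.chisquare(list(observed), f_exp=f_exp)
    return float(res.statistic), float(res.pvalue)
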