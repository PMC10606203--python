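# Methods

## Problem and model

A-to-I RNA editing deaminates adenosine to inosine, which sequencers read as
guanosine, so an edited position appears as an A→G variant on individual
reads. Because editing acts on RNA molecules rather than on the genome, two
nearby editing sites can be co-edited on the same molecule, and any read
spanning both sites phases them directly: each co-covering read carries one
of the four haplotypes AA, AG, GA, GG (front call, rear call, in 5'→3'
transcript order). `editlink` measures the linkage between editing sites
from exactly this read-level signal.

A **pair of editing sites (PES)** is two known same-strand sites co-covered
by at least one read with an A/G call at both positions and at least one
edited call among those reads (f_AA < 1). A pair whose co-covering reads are
all AA is unobservable as a pair — any editing at its sites was seen only on
reads that do not span both — and is discarded rather than recorded as a
zero-LD pair.

### LD statistics

For a PES with haplotype frequencies f_AA, f_AG, f_GA, f_GG and marginal
edited fractions p1 = f_GA + f_GG, p2 = f_AG + f_GG:

    D  = f_GG − p1·p2
    r² = D² / (p1(1−p1) p2(1−p2))

r² is algebraically the squared Pearson correlation of the two per-read
binary edited indicators, and N·r² is the Pearson chi-square statistic of
the 2×2 haplotype table; significance is the χ² = N·r² tail on 1 df (an
exact Fisher alternative on the haplotype table is provided, χ² is the
default). When either marginal is 0 or 1 among co-covering reads, r² is 0/0:
it is reported as NaN and excluded from summaries, not coerced to 0. The
marginals double as the editing levels of the two sites
(level1 = (GA+GG)/N, level2 = (AG+GG)/N). PES "coverage" is N, the number of
co-covering reads with A/G calls at both sites — the sample size of the LD
test.

### Distance, frame, and pair types

Distance between same-gene exonic sites is measured in **spliced transcript
coordinates** (the mRNA is where adjacency and reading frame are defined;
two sites flanking an intron are adjacent in the molecule ADAR edits).
Genomic distance is used for intronic/intergenic pairs. CDS pairs are binned
into distance groups 1–6 (d = 1, 2, 3, 3n+1, 3n+2, 3n+3 for n > 0) and
frame types by the positional rule — codon positions 1–2 nonsynonymous,
position 3 synonymous — applied to (front, rear): type 1 Nonsyn-Nonsyn,
2 Nonsyn-Syn, 3 Syn-Nonsyn, 4 Syn-Syn. Adjacent (d=1) pairs can only be
types 1–3. Site-level Nonsyn/Syn counting uses the **true codon-table
effect** instead (the positional rule's exceptions are ATA→ATG Ile→Met and
TGA→TGG stop→Trp at position 3, both truly nonsynonymous, plus a handful of
truly-synonymous position-1/2 edits such as TAA→TGA stop→stop; stop→stop is
counted synonymous, stop→amino-acid nonsynonymous).

### Neutral expectations

Two genomic null models, each over one (longest-CDS) transcript per gene:

* every unedited CDS adenosine hypothetically changed A→G and classified by
  the true codon-table effect, giving the expected Nonsyn/Syn ratio of a
  neutral editome (known editing sites are excluded when supplied; a scope
  flag restricts to genes containing at least one editing site);
* every adjacent AA dinucleotide in spliced CDS classified by the frame
  type of its two positions, giving the expected type mix of adjacent
  pairs. Overlapping occurrences all count (AAA yields one type-1 and one
  type-2 pair), since each adjacent adenosine pair is a potential PES.

Observed-vs-expected comparisons use Fisher's exact test (two-sided,
conventional at-most-as-probable rule) for the 2×2 Nonsyn/Syn table and a
Pearson chi-square goodness-of-fit (k−1 df, expectation rescaled to the
observed total) for the type mix.

### Drivers and passengers

ADAR prefers a 3-mer context whose downstream neighbor favors G. In an
adjacent Syn-Nonsyn (type-3) pair, editing the rear site creates an AG
context for the front site, so the rear nonsynonymous site is the *driver*
and the front synonymous site the *passenger*, edited by hitchhiking. The
observable footprint is haplotype asymmetry: f_AG (driver-only molecules)
exceeds f_GA (passenger-only molecules), tested with a paired Wilcoxon
signed-rank across pairs of a type. Passengers are defined as **all** front
sites of group-1 type-3 pairs (a stricter per-pair f_AG > f_GA filter is
available behind a flag but is not the default, because the cohort-level
test, not each noisy pair, establishes the mechanism). Excluding passengers
from the observed Syn count can only raise the observed Nonsyn/Syn ratio —
the sense in which linkage causes the adaptive signal of nonsynonymous
editing to be *underestimated*.

Cross-type r² comparisons use unpaired rank-sum tests; because "rank-sum
under bootstrap" is ambiguous, both the plain test and a bootstrap summary
(resample pairs with replacement, report the median replicate p and the
fraction of replicates significant at 0.05) are emitted, neither
privileged. Conservation comparisons (passenger-Syn vs other Syn sites,
type-3 Nonsyn vs other Nonsyn) are unpaired rank-sum tests on per-site
scores supplied as a generic (chrom, pos, score) table; phyloP extraction
from browser tracks is out of scope.

## Synthetic data generator

The generator exists so that every stage runs and is testable with no
download. It emulates:

* a small chromosome (default two genes, alternating strands, four exons
  each, 4.8 kb CDS, 1 kb UTRs, 600 bp introns, 2 kb intergenic flanks) with
  valid ORFs (ATG start, no internal stop);
* adjacent editing-site pairs planted in CDS (types 1–3 via codon templates
  rewritten into the genome so both positions are coding-strand adenosines
  with the frame-dictated effects), 3' UTRs, introns, and intergenic space
  — 10 of each kind by default, spaced more than a read length apart so no
  read spans two pairs;
* the conditional editing mechanism: the driver site is edited with
  probability e2, the passenger with probability e1_hi on driver-edited
  molecules and e1_lo otherwise, giving f_GG = e2·e1_hi, f_AG = e2·(1−e1_hi),
  f_GA = (1−e2)·e1_lo, f_AA = (1−e2)·(1−e1_lo). Defaults e2 = 0.7,
  e1_hi = 0.9, e1_lo = 0.05 reproduce the adjacent-pair regime seen in fly
  brain data — rear-site editing level around 70% with strong coupling and
  f_AG ≫ f_GA. Types 2–3 and non-CDS pairs use a rear driver (AA→AG→GG);
  type 1 defaults to the front-driver mirror (AA→GA→GG), matching the
  direction observed for Nonsyn-Nonsyn pairs, and is configurable;
* pre-aligned reads: single-end 150 nt (a read-length convention chosen
  once; fragment-length modeling is deliberately absent), emitted directly
  as coordinate-sorted SAM with correct spliced CIGARs — exonic pairs yield
  N-gapped reads in transcript space, intron/intergenic pairs contiguous
  pre-mRNA reads. On minus-strand genes an edited base appears as C on the
  forward genome strand. Optional base errors flip the edited state at
  assayed sites with probability base_error (other substitution classes are
  invisible to the binary A/G analysis and are not modeled);
* per-site conservation scores drawn from class-specific normals
  (passenger-Syn mean 1.5 vs other-Syn 0.0, sd 1, Nonsyn classes equal at
  2.0), emulating the observation that passenger synonymous sites are more
  conserved than free-standing ones while type-3 nonsynonymous sites are
  not special among nonsynonymous sites.

What the generator does **not** emulate — and hence what green tests do not
establish about real data: alignment and mapping error (reads are emitted
pre-aligned), quality strings, PCR duplicates, isoform mixtures, SNP
contamination of the site list, clusters of more than two sites per read,
editing-level heterogeneity across sites within a run, or a realistic
genome-wide Nonsyn/Syn background (the toy background ratio is whatever the
random codons give, ~2.4, not the fly genome's 3.97). The generator
validates the machinery — extraction, tallying, statistics — not the
biological conclusions.

Everything is driven by one integer seed; a fixed seed gives byte-identical
FASTA/GFF3/SAM/TSV outputs and pipeline reports (no timestamps are written).

## Numerical choices

* Monomorphic margins: r² and its p reported as NaN, excluded from
  summaries (documented in output columns), never 0.
* All-equal samples in the signed-rank test return p = 1 rather than an
  error; cohorts under 5 pairs are tested but logged with a warning.
* Chi-square goodness-of-fit errors out if a category has zero expectation
  but nonzero observation; expectation is rescaled to the observed total.
* The null-calibration check of LD p-values uses per-pair coverage 1000,
  inside the asymptotic regime of the χ² = N·r² approximation; at low
  coverage the discreteness of counts makes exact uniformity unattainable
  for any test.
* Paired-end data: mates sharing a read name are treated as one molecule;
  conflicting duplicate calls at a site within one molecule become "other".
* Reads with an "other" call at one site of a pair are excluded from that
  pair's tally only, not globally.
* No mapping-quality or base-quality thresholds by default (configurable);
  no maximum pair distance beyond what co-coverage enforces.

## Analysis scripts and problem sizes

`analysis/01–06` run the narrative end to end on the default synthetic
dataset (2 genes, 60 pairs, coverage 200, seed 1; ~12,000 reads, a few
seconds per step), writing tables under `results/` and bulky simulated data
under `scratch/`. The test suite and `scripts/acceptance.py` regenerate
everything they need at the same scale; the power and calibration checks
use 100 replicate cohorts of 30 pairs at coverage 100 and 1000 simulated
pairs at coverage 1000 respectively.

## Known limitations

* The LD p-value procedure of the original fly analysis is not printed in
  full; χ² = N·r² is the canonical choice for the cited LD literature and
  the Fisher alternative is provided. Published per-pair p-values are not
  reproduced here (the underlying reads are not shipped), only the printed
  summary statistics, which this package re-derives exactly from the
  printed counts.
* One transcript per gene; alternative splicing, selenocysteine readthrough
  and overlapping reading frames are out of scope.
* The per-type editing-level spectrum of real data (type-1/2 levels ≤ 30%,
  type-3 ~70%) is collapsed to a single (e2, e1_hi, e1_lo) triple per
  simulation run; cohort-specific regimes are obtained by separate runs.
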