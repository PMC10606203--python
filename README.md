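# editlink

Linkage between A-to-I RNA editing sites, measured directly on sequencing
reads, and its consequence for the adaptive signal of nonsynonymous editing.

A-to-I editing converts adenosine to inosine, read as guanosine, so each
read shows A (unedited) or G (edited) at a known editing site. Two sites
co-covered by reads form a **pair of editing sites (PES)**; each spanning
read carries one of the haplotypes AA, AG, GA, GG, and from the haplotype
frequencies the package computes two-locus linkage disequilibrium

    D = f_GG − p1·p2,   r² = D² / (p1(1−p1) p2(1−p2)),

with p1 = f_GA + f_GG, p2 = f_AG + f_GG (which are also the two sites'
editing levels) and significance from χ² = N·r² on 1 df. Adjacent CDS pairs
are typed by reading frame (Nonsyn-Nonsyn, Nonsyn-Syn, Syn-Nonsyn, Syn-Syn).
In Syn-Nonsyn pairs an excess of AG over GA haplotypes marks the rear
nonsynonymous site as the *driver* whose editing creates a favorable ADAR
context, and the front synonymous site as a hitchhiking *passenger*.
Excluding passenger Syn sites raises the observed Nonsyn/Syn ratio relative
to the genomic neutral expectation (all unedited CDS adenosines changed
A→G), i.e. the usual site-by-site analysis *underestimates* the adaptive
signal of nonsynonymous editing.

The package is written for molecular-evolution researchers working on RNA
editomes: it consumes a genome FASTA, GFF3 gene models, an editing-site TSV
and spliced SAM alignments, and ships a synthetic-data generator so the
entire pipeline runs and is testable without any download.

## Worked example

```
python analysis/01_simulate.py        # synthetic genome + reads -> scratch/
python analysis/02_discover_pairs.py  # PES discovery -> results/pes.tsv
python analysis/05_driver_passenger.py
python analysis/06_adaptive_signal.py
```

`05_driver_passenger.py` prints, for the adjacent CDS pairs of the default
simulation (seed 1, 10 pairs per frame type, coverage 200):

```
type 1: median f_AG=0.015 f_GA=0.083 GA>=AG p=0.00195
type 2: median f_AG=0.080 f_GA=0.010 AG>GA p=0.00195
type 3: median f_AG=0.087 f_GA=0.013 AG>GA p=0.00195
10 passenger Syn sites (front of adjacent Syn-Nonsyn pairs); ...
```

Types 2–3 show the rear-driver asymmetry (f_AG > f_GA) and type 1 the
front-driver mirror image — exactly the trajectories the simulator planted
(driver editing level 0.7, passenger conditional probabilities 0.9/0.05).
`06_adaptive_signal.py` then prints:

```
observed 40/20 = 2.00 vs genomic expectation 1628/665 = 2.45 (Fisher p=0.473)
excluding 10 passengers: 40/10 = 4.00 (Fisher p=0.206) — the ratio rises,
amplifying the adaptive signal
conservation: passenger-Syn median 1.43 vs other-Syn 0.12 (rank-sum p=0.014)
```

followed by the published fly-brain editome statistics re-derived from
their raw counts: 678/144 = 4.71 observed vs 11,862,949/2,988,735 = 3.97
expected (Fisher p = 0.068), and 678/118 = 5.75 after removing the 26
passenger Syn sites (p = 1.4 × 10⁻⁴); the adjacent-pair type mix (21, 7, 26)
differs from the genomic AA-dinucleotide background with χ² p = 2.4 × 10⁻⁵.

The same stages are available as a CLI (`editlink simulate|extract|pair|
ld|classify|expectation|adaptive|run|ref-tables`); `editlink run --out DIR
--seed N` executes everything and writes a JSON report, byte-identical for
a fixed seed.

## Layout

- `src/editlink/` — library: `sim` (synthetic data), `discovery` (PES
  discovery), `ld` (LD statistics), `codon` (frame annotation),
  `expectation` (genomic null models), `adaptive` (driver/passenger and
  ratio tests), `editome` (published fly-brain counts), `pipeline`, `cli`.
- `analysis/01–06` — numbered narrative drivers over the library.
- `tests/` — unit, property (hypothesis) and acceptance suites with
  independent brute-force oracles.
- `docs/methods.md` — model, assumptions, parameter defaults, limitations.
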