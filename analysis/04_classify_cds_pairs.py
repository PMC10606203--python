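#!/usr/bin/env python
"""Classify CDS PESs by spliced distance group and reading-frame type.

Maps each CDS site to its codon position, types each pair (1 Nonsyn-Nonsyn,
2 Nonsyn-Syn, 3 Syn-Nonsyn, 4 Syn-Syn by the frame rule), and compares the
observed adjacent-pair type mix against the genomic adjacent-AA background
expectation with a chi-square goodness-of-fit test.
"""

import pandas as pd

from editlink._tables import pes_from_table
from editlink.codon import classify_cds_pairs, group_type_table
from editlink.expectation import chi_square_gof, expected_aa_types
from editlink.models import read_fasta, read_gff3

genome = read_fasta("scratch/simdata/genome.fa")
models = read_gff3("scratch/simdata/models.gff3")
pes_list = pes_from_table(pd.read_csv("results/pes.tsv", sep="\t"))

classified = classify_cds_pairs(pes_list, genome, models)
counts, fractions = group_type_table([c for _, c in classified])
counts.reset_index().to_csv("results/group_type_counts.tsv", sep="\t",
                            index=False)

print("CDS PES counts (distance group x frame type):")
print(counts.to_string())
aa = expected_aa_types(genome, models)
obs_g1 = [int(counts.loc[1, t]) for t in (1, 2, 3)]
chi2, p = chi_square_gof(obs_g1, aa)
print(f"adjacent-AA background (types 1,2,3): {aa}")
print(f"group-1 observed {obs_g1} vs background mix: chi2={chi2:.2f} "
      f"p={p:.3g}")
print("the generator plants types 1-3 in equal numbers, so unlike the fly "
      "data the synthetic group-1 mix is close to uniform")
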