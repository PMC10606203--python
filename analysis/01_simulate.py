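#!/usr/bin/env python
"""Generate the synthetic dataset every later step consumes.

Builds a two-gene toy chromosome, plants 60 adjacent editing-site pairs
(10 each of CDS frame types 1-3, UTR, intron, intergenic) under the
driver→passenger editing mechanism, and writes genome FASTA, GFF3/BED12
gene models, site/truth tables, coordinate-sorted SAM alignments and
per-site conservation scores under scratch/simdata/.
"""

import sys

from editlink.sim import SimConfig, simulate_dataset, write_dataset

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
cfg = SimConfig(seed=seed)
ds = simulate_dataset(cfg)
paths = write_dataset(ds, "scratch/simdata")

print(f"seed={seed}: {len(ds.pairs)} pairs, {len(ds.reads)} reads")
for k, v in paths.items():
    print(f"  {k}: {v}")
print("driver mechanism: rear site for types 2-3/UTR/intron/other, "
      f"front site for type 1; e2={cfg.e2}, e1_hi={cfg.e1_hi}, "
      f"e1_lo={cfg.e1_lo}, coverage={cfg.coverage}")
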