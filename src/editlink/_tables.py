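"""Round-tripping PES records through their TSV representation."""

from __future__ import annotations

import pandas as pd

from .core import PES, EditingSite, HaplotypeCounts


def pes_from_table(df: pd.DataFrame) -> list[PES]:
    required = {"chrom", "pos1", "pos2", "strand",
                "n_AA", "n_AG", "n_GA", "n_GG"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PES table missing columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        cat = str(r["category"]) if "category" in df.columns else "other"
        s1 = EditingSite(str(r["chrom"]), int(r["pos1"]), str(r["strand"]),
                         cat if cat in ("CDS", "UTR", "intron") else "other")
        s2 = EditingSite(str(r["chrom"]), int(r["pos2"]), str(r["strand"]),
                         s1.region)
        counts = HaplotypeCounts(int(r["n_AA"]), int(r["n_AG"]),
                                 int(r["n_GA"]), int(r["n_GG"]))
        distance = int(r["distance"]) if "distance" in df.columns else abs(
            int(r["pos2"]) - int(r["pos1"]))
        kind = str(r["distance_kind"]) if "distance_kind" in df.columns \
            else "genomic"
        out.append(PES(s1, s2, counts, distance, cat, kind))
    return out
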