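"""Independent brute-force oracles the tests compare the package against.

Deliberately naive: plain double loops and string scans with no shared code
paths with the implementation.
"""

from collections import defaultdict

import numpy as np

CODON_TABLE = {}


def _build_codon_table():
    # standard nuclear code, written out by hand
    aas = (
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    )
    bases = "TCAG"
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_build_codon_table()


def brute_force_effect(codon, codon_pos):
    """Syn/Nonsyn of A→G at codon_pos via a hand-written codon table."""
    assert codon[codon_pos - 1] == "A"
    edited = codon[: codon_pos - 1] + "G" + codon[codon_pos:]
    return "Syn" if CODON_TABLE[codon] == CODON_TABLE[edited] else "Nonsyn"


def brute_force_nonsyn_syn(cds_seq):
    """Enumerate every A in a CDS string against the codon table."""
    n_nonsyn = n_syn = 0
    for i, b in enumerate(cds_seq):
        if b != "A":
            continue
        cp = i % 3 + 1
        codon = cds_seq[i - i % 3 : i - i % 3 + 3]
        if brute_force_effect(codon, cp) == "Nonsyn":
            n_nonsyn += 1
        else:
            n_syn += 1
    return n_nonsyn, n_syn


def brute_force_aa_types(cds_seq):
    """Scan a CDS string for overlapping 'AA' and bin by frame."""
    counts = [0, 0, 0]
    for i in range(len(cds_seq) - 1):
        if cds_seq[i : i + 2] == "AA":
            counts[i % 3] += 1
    return tuple(counts)


def brute_force_pairs(read_calls, strand_of):
    """Double loop over (read x site-pair): tally haplotypes and keep pairs
    with at least one non-AA co-covering read.

    ``read_calls``: {read_id: {site_key: call}} with site_key =
    (chrom, pos, strand); calls already on the coding strand.
    Returns {(front_key, rear_key): (n_AA, n_AG, n_GA, n_GG)} with front the
    5' site on the strand.
    """
    all_sites = sorted({k for calls in read_calls.values() for k in calls})
    tallies = defaultdict(lambda: [0, 0, 0, 0])
    idx = {"AA": 0, "AG": 1, "GA": 2, "GG": 3}
    for i, sa in enumerate(all_sites):
        for sb in all_sites[i + 1 :]:
            if sa[0] != sb[0] or sa[2] != sb[2]:
                continue
            front, rear = (sa, sb) if sa[2] == "+" else (sb, sa)
            for calls in read_calls.values():
                ca, cb = calls.get(front), calls.get(rear)
                if ca in ("A", "G") and cb in ("A", "G"):
                    tallies[(front, rear)][idx[ca + cb]] += 1
    return {
        k: tuple(v)
        for k, v in tallies.items()
        if sum(v) > 0 and v[0] < sum(v)  # f_AA < 1
    }


def brute_force_r2(front_indicators, rear_indicators):
    """r² as the squared Pearson correlation of per-read binary edited
    indicators."""
    x = np.asarray(front_indicators, float)
    y = np.asarray(rear_indicators, float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)
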