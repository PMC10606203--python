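"""Published counts from the D. melanogaster brain editome.

The fly brain editome records 678 nonsynonymous and 144 synonymous CDS
editing sites; the genomic neutral expectation (every CDS adenosine changed
A→G) is 11,862,949 nonsynonymous vs 2,988,735 synonymous changes. Among the
54 adjacent (distance-1) CDS site pairs, 21 are Nonsyn-Nonsyn (type 1), 7
Nonsyn-Syn (type 2) and 26 Syn-Nonsyn (type 3), against a genome-wide
adjacent-AA background of 754,666 / 412,912 / 338,895. The 26 type-3 front
sites are the passenger synonymous sites.

This module re-derives every statistic from those counts at run time with
the package's own test machinery — nothing here is a stored result.
"""

from __future__ import annotations

import pandas as pd

from .adaptive import nonsyn_syn_test
from .expectation import chi_square_gof

FLY_BRAIN_COUNTS = {
    "obs_nonsyn": 678,
    "obs_syn": 144,
    "exp_nonsyn": 11_862_949,
    "exp_syn": 2_988_735,
    "n_passengers": 26,
    "group1_types": (21, 7, 26),  # types 1, 2, 3 among adjacent CDS pairs
    "expected_aa_types": (754_666, 412_912, 338_895),
}


def reference_tables(counts: dict | None = None) -> pd.DataFrame:
    """Recompute the headline statistics of the fly-brain analysis from the
    published raw counts: Nonsyn/Syn ratios before and after passenger
    exclusion with their Fisher exact p-values, and the chi-square
    goodness-of-fit of the adjacent-pair type mix against the genomic
    adjacent-AA background."""
    c = counts or FLY_BRAIN_COUNTS
    rows = []

    full = nonsyn_syn_test(c["obs_nonsyn"], c["obs_syn"],
                           c["exp_nonsyn"], c["exp_syn"])
    rows.append(("obs_nonsyn_syn_ratio", full.ratio_obs,
                 c["obs_nonsyn"] + c["obs_syn"]))
    rows.append(("exp_nonsyn_syn_ratio", full.ratio_exp,
                 c["exp_nonsyn"] + c["exp_syn"]))
    rows.append(("fisher_p_all_sites", full.p_value,
                 c["obs_nonsyn"] + c["obs_syn"]))

    syn_kept = c["obs_syn"] - c["n_passengers"]
    excl = nonsyn_syn_test(c["obs_nonsyn"], syn_kept,
                           c["exp_nonsyn"], c["exp_syn"])
    rows.append(("excl_nonsyn_syn_ratio", excl.ratio_obs,
                 c["obs_nonsyn"] + syn_kept))
    rows.append(("fisher_p_passengers_excluded", excl.p_value,
                 c["obs_nonsyn"] + syn_kept))

    chi2, p_gof = chi_square_gof(c["group1_types"], c["expected_aa_types"])
    n_group1 = sum(c["group1_types"])
    rows.append(("chi2_group1_vs_background", chi2, n_group1))
    rows.append(("chi2_p_group1_vs_background", p_gof, n_group1))

    rows.append(("group1_type3_fraction_pct",
                 100.0 * c["group1_types"][2] / n_group1, n_group1))
    n_aa = sum(c["expected_aa_types"])
    rows.append(("expected_type1_fraction_pct",
                 100.0 * c["expected_aa_types"][0] / n_aa, n_aa))

    return pd.DataFrame(rows, columns=["quantity", "value", "n"])
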