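"""Two-locus linkage disequilibrium on read-level haplotypes.

With haplotype frequencies f_AA, f_AG, f_GA, f_GG and marginal edited
fractions p1 = f_GA + f_GG (front) and p2 = f_AG + f_GG (rear), the coupling
disequilibrium is D = f_GG − p1·p2 and

    r² = D² / (p1 (1−p1) p2 (1−p2)),

the squared correlation of the two per-read edited/unedited indicators.
Significance uses the classical χ² = N·r² statistic on 1 df. When either
site is monomorphic among co-covering reads r² is undefined (0/0) and is
reported as NaN, excluded from distribution summaries rather than coerced
to zero. The marginals double as the editing levels of the two sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import PES, HaplotypeCounts


@dataclass(frozen=True)
class LDResult:
    f_AA: float
    f_AG: float
    f_GA: float
    f_GG: float
    p1: float
    p2: float
    D: float
    r2: float  # NaN when undefined
    p_value: float  # NaN when r2 undefined
    level1: float
    level2: float
    n: int


def ld_r2(counts: HaplotypeCounts) -> LDResult:
    """LD statistics of one ordered site pair."""
    n = counts.total
    if n == 0:
        raise ValueError("no co-covering reads: LD undefined")
    f_aa, f_ag, f_ga, f_gg = counts.frequencies
    p1 = f_ga + f_gg
    p2 = f_ag + f_gg
    D = f_gg - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    if denom == 0.0:
        r2 = float("nan")
        p = float("nan")
    else:
        r2 = D * D / denom
        p = ld_pvalue_from_r2(r2, n)
    return LDResult(f_aa, f_ag, f_ga, f_gg, p1, p2, D, r2, p, p1, p2, n)


def ld_pvalue_from_r2(r2: float, n: int) -> float:
    """Two-sided LD significance: χ² = N·r² on 1 df."""
    return float(stats.chi2.sf(n * r2, df=1))


def ld_pvalue(counts: HaplotypeCounts, method: str = "chi2") -> float:
    """LD p-value for a haplotype table.

    ``chi2`` (default) is χ² = N·r² on 1 df; ``fisher`` is the exact test on
    the 2×2 haplotype count table. NaN when r² is undefined.
    """
    res = ld_r2(counts)
    if math.isnan(res.r2):
        return float("nan")
    if method == "chi2":
        return res.p_value
    if method == "fisher":
        table = [[counts.n_AA, counts.n_AG], [counts.n_GA, counts.n_GG]]
        return float(stats.fisher_exact(table).pvalue)
    raise ValueError(f"unknown method {method!r}")


def editing_levels(counts: HaplotypeCounts) -> tuple[float, float]:
    """(level1, level2): edited-read fraction at the front and rear site
    among co-covering reads."""
    n = counts.total
    if n == 0:
        raise ValueError("no co-covering reads: levels undefined")
    return (counts.n_GA + counts.n_GG) / n, (counts.n_AG + counts.n_GG) / n


def ld_table(pes_list: list[PES]) -> pd.DataFrame:
    """One row of LD statistics per PES."""
    rows = []
    for p in pes_list:
        r = ld_r2(p.counts)
        rows.append(
            {
                "chrom": p.site1.chrom,
                "pos1": p.site1.pos,
                "pos2": p.site2.pos,
                "strand": p.site1.strand,
                "category": p.category,
                "distance": p.distance,
                "n": r.n,
                "f_AA": r.f_AA,
                "f_AG": r.f_AG,
                "f_GA": r.f_GA,
                "f_GG": r.f_GG,
                "p1": r.p1,
                "p2": r.p2,
                "D": r.D,
                "r2": r.r2,
                "p_value": r.p_value,
                "level1": r.level1,
                "level2": r.level2,
            }
        )
    return pd.DataFrame(rows)


CATEGORY_ORDER = ("CDS", "UTR", "intron", "other")


def summarize_by_category(pes_list: list[PES], alpha: float = 0.05) -> dict:
    """Per-category LD summary and cross-category comparisons.

    Returns a dict with:
      * ``by_category``: count, median r² (defined pairs only), fraction of
        significant pairs (p < alpha), and Fisher exact p of that fraction
        against the CDS category;
      * ``spearman``: (rho, p) between distance and r² over all defined pairs;
      * ``pairwise``: rank-sum p-values comparing r², distance, and coverage
        distributions between every category pair.
    """
    df = ld_table(pes_list)
    if df.empty:
        raise ValueError("no PESs to summarize")
    defined = df[df["r2"].notna()]

    rows = []
    sig_counts: dict[str, tuple[int, int]] = {}
    for cat in CATEGORY_ORDER:
        sub = defined[defined["category"] == cat]
        if sub.empty:
            continue
        n_sig = int((sub["p_value"] < alpha).sum())
        sig_counts[cat] = (n_sig, len(sub))
        rows.append(
            {
                "category": cat,
                "n_pes": int((df["category"] == cat).sum()),
                "n_defined": len(sub),
                "median_r2": float(sub["r2"].median()),
                "frac_significant": n_sig / len(sub),
            }
        )
    by_cat = pd.DataFrame(rows)
    if "CDS" in sig_counts:
        cds_sig, cds_n = sig_counts["CDS"]
        fisher_ps = []
        for _, row in by_cat.iterrows():
            s, n = sig_counts[row["category"]]
            p = stats.fisher_exact(
                [[s, n - s], [cds_sig, cds_n - cds_sig]]
            ).pvalue
            fisher_ps.append(float(p))
        by_cat["fisher_p_vs_CDS"] = fisher_ps

    if len(defined) >= 3 and defined["distance"].nunique() > 1:
        rho, sp_p = stats.spearmanr(defined["distance"], defined["r2"])
        spearman = (float(rho), float(sp_p))
    else:
        spearman = (float("nan"), float("nan"))

    pw_rows = []
    for a, b in combinations(by_cat["category"], 2):
        da = defined[defined["category"] == a]
        db = defined[defined["category"] == b]
        entry = {"cat_a": a, "cat_b": b}
        for col, name in (("r2", "p_r2"), ("distance", "p_distance"),
                          ("n", "p_coverage")):
            if len(da) and len(db):
                entry[name] = float(
                    stats.mannwhitneyu(da[col], db[col],
                                       alternative="two-sided").pvalue
                )
            else:
                entry[name] = float("nan")
        pw_rows.append(entry)

    return {
        "by_category": by_cat,
        "spearman": spearman,
        "pairwise": pd.DataFrame(pw_rows),
        "alpha": alpha,
    }
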