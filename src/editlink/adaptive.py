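"""Driver/passenger analysis and the Nonsyn/Syn adaptive signal.

In an adjacent Syn-Nonsyn (type-3) pair the rear nonsynonymous site is the
driver — its editing creates a favorable 5'-neighbor context — and the front
synonymous site is the passenger edited as a byproduct (hitchhiking). The
footprint of this mechanism is haplotype asymmetry, f_AG > f_GA: molecules
where only the driver is edited outnumber molecules where only the
passenger is. Excluding passenger Syn sites from the observed editome raises
the Nonsyn/Syn ratio relative to the genomic neutral expectation, i.e. the
adaptive signal of nonsynonymous editing is amplified.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codon import PesClass
from .core import PES, EditingSite
from .ld import ld_r2

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PassengerSet:
    """Front (passenger, Syn) and rear (driver, Nonsyn) sites of adjacent
    Syn-Nonsyn pairs."""

    passengers: tuple[EditingSite, ...]
    drivers: tuple[EditingSite, ...]

    def __len__(self) -> int:
        return len(self.passengers)


def identify_passengers(
    classified: list[tuple[PES, PesClass]],
    require_asymmetry: bool = False,
) -> PassengerSet:
    """All front sites of group-1 type-3 pairs, deduplicated.

    ``require_asymmetry`` additionally demands f_AG > f_GA within the pair
    (a stricter, per-pair driver criterion).
    """
    passengers: dict[tuple, EditingSite] = {}
    drivers: dict[tuple, EditingSite] = {}
    for pes, cls in classified:
        if cls.group != 1 or cls.pes_type != 3:
            continue
        if require_asymmetry:
            r = ld_r2(pes.counts)
            if not r.f_AG > r.f_GA:
                continue
        passengers.setdefault(pes.site1.key, pes.site1)
        drivers.setdefault(pes.site2.key, pes.site2)
    return PassengerSet(tuple(passengers.values()), tuple(drivers.values()))


def compare_haplotype_asymmetry(pes_list: list[PES]) -> dict:
    """Paired signed-rank test of f_AG vs f_GA across pairs of one type.

    Returns medians, the direction, and the two-sided p (1.0 when every pair
    has f_AG = f_GA, and NaN for an empty cohort).
    """
    if not pes_list:
        raise ValueError("no PESs given")
    f_ag = np.array([ld_r2(p.counts).f_AG for p in pes_list])
    f_ga = np.array([ld_r2(p.counts).f_GA for p in pes_list])
    if len(pes_list) < 5:
        log.warning("haplotype asymmetry test on only %d pairs", len(pes_list))
    if np.all(f_ag == f_ga):
        p = 1.0
    else:
        p = float(stats.wilcoxon(f_ag, f_ga).pvalue)
    return {
        "n": len(pes_list),
        "median_f_AG": float(np.median(f_ag)),
        "median_f_GA": float(np.median(f_ga)),
        "direction": "AG>GA" if np.median(f_ag - f_ga) > 0 else "GA>=AG",
        "p_value": p,
    }


@dataclass(frozen=True)
class RatioTest:
    n_obs_nonsyn: int
    n_obs_syn: int
    n_exp_nonsyn: int
    n_exp_syn: int
    ratio_obs: float
    ratio_exp: float
    odds_ratio: float
    p_value: float  # two-sided Fisher exact


def nonsyn_syn_test(
    n_obs_nonsyn: int,
    n_obs_syn: int,
    n_exp_nonsyn: int,
    n_exp_syn: int,
) -> RatioTest:
    """Observed vs expected Nonsyn/Syn ratio, Fisher exact on the 2×2 table
    [[obs_N, obs_S], [exp_N, exp_S]]."""
    odds, p = stats.fisher_exact(
        [[n_obs_nonsyn, n_obs_syn], [n_exp_nonsyn, n_exp_syn]],
        alternative="two-sided",
    )
    return RatioTest(
        n_obs_nonsyn=n_obs_nonsyn,
        n_obs_syn=n_obs_syn,
        n_exp_nonsyn=n_exp_nonsyn,
        n_exp_syn=n_exp_syn,
        ratio_obs=n_obs_nonsyn / n_obs_syn if n_obs_syn else math.inf,
        ratio_exp=n_exp_nonsyn / n_exp_syn if n_exp_syn else math.inf,
        odds_ratio=float(odds),
        p_value=float(p),
    )


def apply_passenger_exclusion(
    n_obs_nonsyn: int, n_obs_syn: int, passengers: PassengerSet,
    site_effects: dict[tuple, str] | None = None,
) -> tuple[int, int]:
    """Remove passenger sites from the observed counts.

    Passengers are synonymous by construction; ``site_effects`` (site key →
    true effect) lets a caller account for any passenger whose true
    codon-table effect is nonsynonymous (the ATA exception).
    """
    n_syn_removed = n_nonsyn_removed = 0
    for site in passengers.passengers:
        eff = (site_effects or {}).get(site.key, "Syn")
        if eff == "Nonsyn":
            n_nonsyn_removed += 1
        else:
            n_syn_removed += 1
    return n_obs_nonsyn - n_nonsyn_removed, n_obs_syn - n_syn_removed


def compare_r2_across_types(
    classified: list[tuple[PES, PesClass]],
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    group: int = 1,
) -> pd.DataFrame:
    """Pairwise rank-sum comparison of r² between pair types within a
    distance group, with an optional bootstrap summary.

    For each type pair the plain two-sided Mann-Whitney p is reported; with
    ``n_boot`` > 0 pairs are resampled with replacement and the median
    replicate p and the fraction of replicates with p < 0.05 are added.
    """
    by_type: dict[int, list[float]] = {}
    for pes, cls in classified:
        if cls.group != group:
            continue
        r2 = ld_r2(pes.counts).r2
        if not math.isnan(r2):
            by_type.setdefault(cls.pes_type, []).append(r2)
    types = sorted(by_type)
    if len(types) < 2:
        raise ValueError("need at least two pair types to compare")
    rng = rng or np.random.default_rng()
    rows = []
    for i, a in enumerate(types):
        for b in types[i + 1 :]:
            xa, xb = np.array(by_type[a]), np.array(by_type[b])
            p_plain = float(
                stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
            )
            row = {
                "type_a": a, "type_b": b,
                "n_a": len(xa), "n_b": len(xb),
                "median_r2_a": float(np.median(xa)),
                "median_r2_b": float(np.median(xb)),
                "p_ranksum": p_plain,
            }
            if n_boot > 0:
                boot_ps = np.empty(n_boot)
                for k in range(n_boot):
                    ra = rng.choice(xa, size=len(xa), replace=True)
                    rb = rng.choice(xb, size=len(xb), replace=True)
                    if np.ptp(ra) == 0 and np.ptp(rb) == 0 and ra[0] == rb[0]:
                        boot_ps[k] = 1.0
                    else:
                        boot_ps[k] = stats.mannwhitneyu(
                            ra, rb, alternative="two-sided"
                        ).pvalue
                row["p_boot_median"] = float(np.median(boot_ps))
                row["frac_boot_significant"] = float((boot_ps < 0.05).mean())
            rows.append(row)
    return pd.DataFrame(rows)


def conservation_compare(
    scores_a: "np.ndarray | list[float]",
    scores_b: "np.ndarray | list[float]",
    label_a: str = "a",
    label_b: str = "b",
) -> dict:
    """Unpaired rank-sum comparison of conservation scores between two site
    partitions (e.g. passenger-Syn vs other Syn sites)."""
    xa, xb = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("empty partition")
    p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
    return {
        "label_a": label_a,
        "label_b": label_b,
        "n_a": len(xa),
        "n_b": len(xb),
        "median_a": float(np.median(xa)),
        "median_b": float(np.median(xb)),
        "p_value": p,
    }


def conservation_partitions(
    truth: pd.DataFrame, conservation: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Join per-site truth classes with a conservation table, returning the
    score vector of each class; sites without a score are dropped (logged)."""
    merged = truth.merge(
        conservation[["chrom", "pos", "score"]], on=["chrom", "pos"],
        how="left",
    )
    n_missing = int(merged["score"].isna().sum())
    if n_missing:
        log.info("dropped %d sites without conservation scores", n_missing)
        merged = merged.dropna(subset=["score"])
    return {
        cls: grp["score"].to_numpy()
        for cls, grp in merged.groupby("cons_class")
    }
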