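"""Driver/passenger identification and the Nonsyn/Syn adaptive signal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from editlink.adaptive import (
    apply_passenger_exclusion,
    compare_haplotype_asymmetry,
    compare_r2_across_types,
    conservation_compare,
    identify_passengers,
    nonsyn_syn_test,
)
from editlink.codon import PesClass
from editlink.core import PES, EditingSite, HaplotypeCounts


def _pes(pos1, pos2, counts, strand="+"):
    return PES(EditingSite("c", pos1, strand, "CDS"),
               EditingSite("c", pos2, strand, "CDS"),
               HaplotypeCounts(*counts), pos2 - pos1, "CDS", "spliced")


def _group1_type3(pos1, counts=(70, 20, 2, 8)):
    return (_pes(pos1, pos1 + 1, counts), PesClass(1, 1, 3))


class TestPassengers:
    def test_front_sites_of_group1_type3(self):
        classified = [_group1_type3(10), _group1_type3(50),
                      (_pes(100, 101, (70, 20, 2, 8)), PesClass(1, 1, 1))]
        ps = identify_passengers(classified)
        assert len(ps) == 2
        assert {s.pos for s in ps.passengers} == {10, 50}
        assert {s.pos for s in ps.drivers} == {11, 51}

    def test_no_type3_empty(self):
        classified = [(_pes(1, 2, (5, 1, 0, 0)), PesClass(1, 1, 1))]
        assert len(identify_passengers(classified)) == 0

    def test_shared_front_site_counted_once(self):
        a = _group1_type3(10)
        b = (_pes(10, 13, (70, 20, 2, 8)), PesClass(3, 3, 3))
        # only group-1 type-3 qualify; duplicate of the same qualifying pair:
        ps = identify_passengers([a, a])
        assert len(ps) == 1

    def test_per_pes_asymmetry_filter(self):
        asym = _group1_type3(10, (70, 20, 2, 8))  # f_AG > f_GA
        sym = _group1_type3(50, (70, 2, 20, 8))  # f_GA > f_AG
        ps = identify_passengers([asym, sym], require_asymmetry=True)
        assert {s.pos for s in ps.passengers} == {10}


class TestAsymmetry:
    def test_equal_frequencies_p_one(self):
        cohort = [_pes(i, i + 1, (80, 10, 10, 0)) for i in range(1, 51, 5)]
        res = compare_haplotype_asymmetry(cohort)
        assert res["p_value"] == 1.0

    def test_single_pair_balanced(self):
        res = compare_haplotype_asymmetry([_pes(1, 2, (80, 10, 10, 0))])
        assert res["p_value"] == 1.0
        assert res["n"] == 1

    def test_detects_planted_direction(self, dataset, discovered_pes):
        from editlink.codon import classify_cds_pairs

        classified = classify_cds_pairs(discovered_pes, dataset.genome,
                                        dataset.models)
        type3 = [p for p, c in classified if c.pes_type == 3 and c.group == 1]
        res = compare_haplotype_asymmetry(type3)
        assert res["direction"] == "AG>GA"
        assert res["p_value"] < 0.05


class TestRatioTest:
    def test_fly_brain_all_sites(self):
        r = nonsyn_syn_test(678, 144, 11_862_949, 2_988_735)
        assert r.ratio_obs == pytest.approx(4.71, abs=0.005)
        assert r.ratio_exp == pytest.approx(3.97, abs=0.005)
        assert r.p_value == pytest.approx(0.067, abs=0.001)

    def test_fly_brain_passengers_excluded(self):
        r = nonsyn_syn_test(678, 118, 11_862_949, 2_988_735)
        assert r.ratio_obs == pytest.approx(5.75, abs=0.005)
        assert r.p_value == pytest.approx(1.40e-4, rel=0.05)

    def test_observed_at_expectation_p_one(self):
        r = nonsyn_syn_test(397, 100, 3_970_000, 1_000_000)
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0, abs=0.05)

    def test_zero_syn_infinite_ratio(self):
        r = nonsyn_syn_test(10, 0, 100, 50)
        assert np.isinf(r.ratio_obs)
        assert 0 < r.p_value <= 1

    def test_chi2_agrees_with_fisher_to_first_digit(self):
        fisher_p = nonsyn_syn_test(678, 144, 11_862_949, 2_988_735).p_value
        chi2_p = stats.chi2_contingency(
            [[678, 144], [11_862_949, 2_988_735]], correction=False
        ).pvalue
        assert abs(fisher_p - chi2_p) < 0.02  # 0.067 vs ~0.06

    @given(st.integers(1, 400), st.integers(1, 200), st.integers(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_exclusion_never_decreases_ratio(self, n_nonsyn, n_syn, n_excl):
        n_excl = min(n_excl, n_syn - 1)
        if n_excl < 0:
            return
        before = n_nonsyn / n_syn
        after = n_nonsyn / (n_syn - n_excl) if n_syn > n_excl else np.inf
        assert after >= before

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 5000),
           st.integers(1, 5000))
    @settings(max_examples=50, deadline=None)
    def test_fisher_invariant_to_double_swap(self, a, b, c, d):
        p1 = nonsyn_syn_test(a, b, c, d).p_value
        p2 = nonsyn_syn_test(d, c, b, a).p_value  # both rows + both cols
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestExclusion:
    def test_syn_passengers_removed(self):
        ps = identify_passengers([_group1_type3(10), _group1_type3(50)])
        assert apply_passenger_exclusion(100, 40, ps) == (100, 38)

    def test_nonsyn_passenger_respects_true_effect(self):
        ps = identify_passengers([_group1_type3(10)])
        eff = {("c", 10, "+"): "Nonsyn"}  # e.g. an ATA pos-3 passenger
        assert apply_passenger_exclusion(100, 40, ps, eff) == (99, 40)


class TestR2AcrossTypes:
    def test_elevated_type3_detected(self):
        rng = np.random.default_rng(0)
        classified = []
        for i in range(20):
            # type 1: weak coupling; type 3: strong coupling
            classified.append(
                (_pes(10 * i + 1, 10 * i + 2, (60, 20, 15, 5)),
                 PesClass(1, 1, 1)))
            classified.append(
                (_pes(1000 + 10 * i, 1000 + 10 * i + 1, (25, 5, 2, 68)),
                 PesClass(1, 1, 3)))
        df = compare_r2_across_types(classified, n_boot=100, rng=rng)
        row = df[(df.type_a == 1) & (df.type_b == 3)].iloc[0]
        assert row["median_r2_b"] > row["median_r2_a"]
        assert row["p_ranksum"] < 0.01
        assert row["frac_boot_significant"] > 0.9

    def test_no_boot(self):
        classified = [
            (_pes(1, 2, (60, 20, 15, 5)), PesClass(1, 1, 1)),
            (_pes(10, 11, (25, 5, 2, 68)), PesClass(1, 1, 3)),
        ]
        df = compare_r2_across_types(classified, n_boot=0)
        assert "p_boot_median" not in df.columns

    def test_single_type_rejected(self):
        with pytest.raises(ValueError):
            compare_r2_across_types([_group1_type3(1)], n_boot=0)


class TestConservation:
    def test_shifted_means_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.5, 1.0, 200)
        b = rng.normal(0.0, 1.0, 200)
        res = conservation_compare(a, b, "passenger-Syn", "other-Syn")
        assert res["p_value"] < 0.01
        assert res["median_a"] > res["median_b"]

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            conservation_compare([], [1.0, 2.0])

    def test_null_p_uniform_over_seeds(self):
        # identical distributions: rank-sum p ~ Uniform(0,1) (KS check)
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            ps.append(conservation_compare(rng.normal(0, 1, 60),
                                           rng.normal(0, 1, 60))["p_value"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01
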