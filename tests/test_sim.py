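"""Synthetic-data generator: determinism, genome validity, truth model."""

import numpy as np
import pytest
from Bio.Seq import Seq

from editlink.core import HaplotypeCounts
from editlink.sim import (
    ConfigError,
    SimConfig,
    generate_genome,
    haplotype_probs,
    place_editing_pairs,
    simulate_conservation,
    simulate_dataset,
    simulate_haplotype_counts,
    write_dataset,
)


class TestGenerateGenome:
    def test_deterministic_fasta_bytes(self, tmp_path):
        cfg = SimConfig(n_genes=2, seed=1)
        out = []
        for name in ("a.fa", "b.fa"):
            ds = simulate_dataset(cfg)
            paths = write_dataset(ds, str(tmp_path / name[0]))
            out.append(open(paths["fasta"], "rb").read())
        assert out[0] == out[1]

    def test_cds_length_multiple_of_three(self, dataset):
        for t in dataset.models:
            assert t.cds_len % 3 == 0

    def test_cds_translates_without_internal_stops(self, dataset):
        for t in dataset.models:
            cds = t.cds_sequence(dataset.genome)
            assert cds.startswith("ATG")
            prot = str(Seq(cds).translate())
            assert prot.endswith("*")
            assert "*" not in prot[:-1]

    def test_bad_cds_length_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(cds_length=100)

    def test_minus_strand_gene_present(self, dataset):
        assert {t.strand for t in dataset.models} == {"+", "-"}


class TestPlacement:
    def test_all_sites_are_coding_strand_adenosines(self, dataset):
        chrom = dataset.genome["chrS"]
        for p in dataset.pairs:
            for st in (p.front, p.rear):
                base = chrom[st.site.pos - 1]
                expected = "A" if p.strand == "+" else "T"
                assert base == expected, p.pair_id

    def test_type3_codon_positions(self, dataset):
        from editlink.codon import cds_context

        for p in dataset.pairs:
            if p.kind != "cds3":
                continue
            cf = cds_context(p.front.site, dataset.genome, dataset.models)
            cr = cds_context(p.rear.site, dataset.genome, dataset.models)
            assert (cf.codon_pos, cr.codon_pos) == (3, 1)
            assert cr.cds_pos - cf.cds_pos == 1

    def test_type1_both_nonsyn_by_position(self, dataset):
        from editlink.codon import cds_context

        for p in dataset.pairs:
            if p.kind != "cds1":
                continue
            for st in (p.front, p.rear):
                ctx = cds_context(st.site, dataset.genome, dataset.models)
                assert ctx.positional == "Nonsyn"

    def test_too_short_cds_raises(self):
        cfg = SimConfig(cds_length=300, utr_length=1000, n_pairs_per_type=10)
        genome, models = generate_genome(cfg)
        from editlink.sim import GenerationError

        with pytest.raises(GenerationError):
            place_editing_pairs(genome, models, cfg)


class TestTruthModel:
    @pytest.mark.parametrize("e2,e1_hi,e1_lo", [
        (0.7, 0.9, 0.05), (0.2, 0.2, 0.2), (0.5, 1.0, 0.0), (0.0, 0.3, 0.1),
    ])
    def test_probs_sum_to_one(self, e2, e1_hi, e1_lo):
        for driver in ("rear", "front"):
            probs = haplotype_probs(e2, e1_hi, e1_lo, driver)
            assert abs(sum(probs) - 1.0) < 1e-12

    def test_closed_form_single_edit_frequencies(self):
        # e2=0.7, e1_hi=0.9, e1_lo=0.05 => f_AG = 0.07, f_GA = 0.015
        f_aa, f_ag, f_ga, f_gg = haplotype_probs(0.7, 0.9, 0.05)
        assert f_ag == pytest.approx(0.07)
        assert f_ga == pytest.approx(0.015)
        assert f_gg == pytest.approx(0.63)

    def test_multinomial_mean_and_asymmetry(self):
        rng = np.random.default_rng(11)
        f_ag, f_ga, wins = [], [], 0
        for _ in range(300):
            c = simulate_haplotype_counts((0.215, 0.07, 0.015, 0.7), 10_000, rng)
            f_ag.append(c.n_AG / c.total)
            f_ga.append(c.n_GA / c.total)
            wins += c.n_AG > c.n_GA
        assert np.mean(f_ag) == pytest.approx(0.07, abs=0.002)
        assert np.mean(f_ga) == pytest.approx(0.015, abs=0.002)
        assert wins / 300 > 0.99

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        c = simulate_haplotype_counts((0.25, 0.25, 0.25, 0.25), 5, rng)
        assert c.total == 5

    def test_independent_sites_r2_shrinks_with_n(self):
        # e1_hi == e1_lo: true D = 0, sampled r2 has mean ~ 1/n
        from editlink.ld import ld_r2

        rng = np.random.default_rng(5)
        probs = haplotype_probs(0.3, 0.25, 0.25)
        for n in (100, 1000):
            r2s = []
            for _ in range(400):
                c = simulate_haplotype_counts(probs, n, rng)
                r = ld_r2(c).r2
                if not np.isnan(r):
                    r2s.append(r)
            assert np.mean(r2s) == pytest.approx(1 / n, rel=0.35)


class TestConservation:
    def test_sd_zero_gives_class_means(self, dataset):
        rng = np.random.default_rng(0)
        classes = [(p.front.site, p.front.cons_class) for p in dataset.pairs]
        means = {"passenger-Syn": 1.5, "other-Syn": 0.0, "type3-Nonsyn": 2.0,
                 "other-Nonsyn": 2.0, "noncoding": -0.5}
        df = simulate_conservation(classes, means, 0.0, rng)
        for _, row in df.iterrows():
            assert row["score"] == means[row["cons_class"]]

    def test_deterministic_under_seed(self, dataset):
        classes = [(p.front.site, p.front.cons_class) for p in dataset.pairs]
        means = {c: 0.0 for _, c in classes}
        a = simulate_conservation(classes, means, 1.0, np.random.default_rng(9))
        b = simulate_conservation(classes, means, 1.0, np.random.default_rng(9))
        assert a.equals(b)

    def test_unknown_class_rejected(self, dataset):
        site = dataset.pairs[0].front.site
        with pytest.raises(ValueError, match="unknown conservation class"):
            simulate_conservation([(site, "mystery")], {"known": 0.0}, 1.0,
                                  np.random.default_rng(0))


class TestReads:
    def test_minus_strand_edited_base_is_C_on_forward(self, dataset):
        # fully edited haplotype on a minus-strand pair must show C at the
        # site on the forward genome strand
        minus = [p for p in dataset.pairs if p.strand == "-"][0]
        by_name = {r["name"]: r for r in dataset.reads}
        found = False
        for r in dataset.reads:
            if not r["name"].startswith(minus.pair_id):
                continue
            gstart = r["pos"]
            gpos = []
            cur = gstart
            import re

            for num, op in re.findall(r"(\d+)([MN])", r["cigar"]):
                if op == "M":
                    gpos.extend(range(cur, cur + int(num)))
                cur += int(num)
            if minus.front.site.pos in gpos:
                base = r["seq"][gpos.index(minus.front.site.pos)]
                assert base in ("C", "T")
                found = found or base == "C"
        assert found  # at least one edited molecule observed

    def test_spliced_cigars_emitted(self, dataset):
        assert any("N" in r["cigar"] for r in dataset.reads)
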