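"""PES discovery: site loading, CIGAR-aware extraction, pairing rules."""

import numpy as np
import pytest

from editlink.core import EditingSite, load_sites
from editlink.discovery import (
    assign_category,
    extract_observations,
    pair_sites,
)
from editlink.models import GeneModels, Interval, Transcript

from oracles import brute_force_pairs


def _sam(tmp_path, records, chrom="chrT", length=10_000):
    path = tmp_path / "toy.sam"
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{chrom}\tLN:{length}",
    ]
    for name, flag, pos, cigar, seq in records:
        lines.append(
            f"{name}\t{flag}\t{chrom}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*"
        )
    path.write_text("\n".join(lines) + "\n")
    return str(path)


class TestLoadSites:
    def test_valid_tsv(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("chrom\tpos\tstrand\nchr1\t10\t+\nchr1\t20\t-\nchr2\t5\t+\n")
        sites = load_sites(str(p))
        assert len(sites) == 3
        assert sites[0].pos == 10

    def test_zero_position_rejected(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("chrom\tpos\tstrand\nchr1\t0\t+\n")
        with pytest.raises(ValueError, match="line 2"):
            load_sites(str(p))

    def test_duplicates_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "sites.tsv"
        p.write_text("chrom\tpos\tstrand\nchr1\t10\t+\nchr1\t10\t+\n")
        with caplog.at_level("WARNING"):
            sites = load_sites(str(p))
        assert len(sites) == 1
        assert "duplicate" in caplog.text


class TestExtract:
    def test_plus_strand_match(self, tmp_path):
        site = EditingSite("chrT", 105, "+")
        sam = _sam(tmp_path, [("r1", 0, 101, "50M", "AAAAG" + "C" * 45)])
        obs = extract_observations(sam, [site])
        assert len(obs) == 1 and obs[0].call == "G"

    def test_minus_strand_complement(self, tmp_path):
        site = EditingSite("chrT", 103, "-")
        sam = _sam(tmp_path, [("r1", 0, 101, "10M", "TTCTTTTTTT")])
        obs = extract_observations(sam, [site])
        assert obs[0].call == "G"  # forward C reads as G on the coding strand

    def test_site_inside_splice_gap_skipped(self, tmp_path):
        site = EditingSite("chrT", 150, "+")  # inside the 100N gap
        sam = _sam(tmp_path, [("r1", 0, 101, "20M100N30M", "A" * 50)])
        assert extract_observations(sam, [site]) == []

    def test_site_in_second_match_block(self, tmp_path):
        site = EditingSite("chrT", 230, "+")  # 221 + 9 into the 30M block
        seq = "A" * 20 + "C" * 9 + "G" + "C" * 20
        sam = _sam(tmp_path, [("r1", 0, 101, "20M100N30M", seq)])
        obs = extract_observations(sam, [site])
        assert obs[0].call == "G"

    def test_secondary_and_unmapped_skipped(self, tmp_path):
        site = EditingSite("chrT", 105, "+")
        sam = _sam(tmp_path, [
            ("r1", 256, 101, "10M", "A" * 10),  # secondary
            ("r2", 4, 101, "10M", "A" * 10),    # unmapped
        ])
        assert extract_observations(sam, [site]) == []

    def test_non_ag_call_labeled_other(self, tmp_path):
        site = EditingSite("chrT", 101, "+")
        sam = _sam(tmp_path, [("r1", 0, 101, "5M", "CAAAA")])
        assert extract_observations(sam, [site])[0].call == "other"


class TestPairing:
    def _obs(self, reads, s1, s2):
        from editlink.core import ReadObservation

        out = []
        for rid, (c1, c2) in reads.items():
            out.append(ReadObservation(rid, s1, c1))
            out.append(ReadObservation(rid, s2, c2))
        return out

    def test_basic_tally(self):
        s1 = EditingSite("c", 10, "+")
        s2 = EditingSite("c", 20, "+")
        obs = self._obs({"a": ("A", "G"), "b": ("A", "A"), "c": ("G", "G")},
                        s1, s2)
        pes = pair_sites(obs)
        assert len(pes) == 1
        c = pes[0].counts
        assert (c.n_AA, c.n_AG, c.n_GA, c.n_GG) == (1, 1, 0, 1)

    def test_all_AA_pair_rejected(self):
        # editing seen only on reads that do not cover the partner site
        from editlink.core import ReadObservation

        s1 = EditingSite("c", 10, "+")
        s2 = EditingSite("c", 20, "+")
        obs = self._obs({"a": ("A", "A"), "b": ("A", "A")}, s1, s2)
        obs.append(ReadObservation("solo", s1, "G"))  # covers s1 only
        assert pair_sites(obs) == []

    def test_other_calls_dropped_per_pair(self):
        s1 = EditingSite("c", 10, "+")
        s2 = EditingSite("c", 20, "+")
        obs = self._obs({"a": ("other", "G"), "b": ("G", "A")}, s1, s2)
        pes = pair_sites(obs)
        assert pes[0].counts.total == 1  # only read b counted

    def test_minus_strand_front_is_downstream(self):
        s1 = EditingSite("c", 10, "-")
        s2 = EditingSite("c", 20, "-")
        obs = self._obs({"a": ("A", "G")}, s1, s2)  # G at the 5' (higher) site
        pes = pair_sites(obs)
        assert pes[0].site1.pos == 20
        assert pes[0].counts.n_GA == 1

    def test_equals_brute_force_oracle(self, dataset, dataset_paths):
        """Pairing must match a naive read x site-pair double loop."""
        from editlink.discovery import extract_observations

        calls = {}
        for o in extract_observations(dataset_paths["sam"], dataset.sites):
            calls.setdefault(o.read_id, {})[o.site.key] = o.call
        keep = set(sorted(calls)[:100])  # <= 100 reads
        calls = {k: v for k, v in calls.items() if k in keep}
        expected = brute_force_pairs(calls, None)
        from editlink.core import ReadObservation

        site_objs = {s.key: s for s in dataset.sites}
        sub_obs = [
            ReadObservation(rid, site_objs[sk], c)
            for rid, d in calls.items()
            for sk, c in d.items()
        ]
        got = {
            ((p.site1.key), (p.site2.key)): (
                p.counts.n_AA, p.counts.n_AG, p.counts.n_GA, p.counts.n_GG)
            for p in pair_sites(sub_obs)
        }
        assert got == expected


class TestCategory:
    @pytest.fixture()
    def toy_models(self):
        t = Transcript(
            gene_id="g", transcript_id="g.t", chrom="c", strand="+",
            exons=(Interval(1, 100), Interval(201, 300)),
            cds=(Interval(31, 100), Interval(201, 260)),
        )
        return GeneModels([t])

    def _pes(self, p1, p2):
        from editlink.core import PES, HaplotypeCounts

        return PES(EditingSite("c", p1, "+"), EditingSite("c", p2, "+"),
                   HaplotypeCounts(1, 1, 0, 0), p2 - p1)

    def test_both_cds(self, toy_models):
        assert assign_category(self._pes(40, 220), toy_models) == "CDS"

    def test_mixed_cds_intron_is_other(self, toy_models):
        assert assign_category(self._pes(40, 150), toy_models) == "other"

    def test_both_utr(self, toy_models):
        assert assign_category(self._pes(5, 20), toy_models) == "UTR"

    def test_both_intron(self, toy_models):
        assert assign_category(self._pes(120, 150), toy_models) == "intron"

    def test_unannotated_is_other(self, toy_models):
        assert assign_category(self._pes(400, 420), toy_models) == "other"
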