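import numpy as np
import pandas as pd
import pytest

import oracles
from cerna_forge.io_formats import AnnotationSet, SequenceSet, Transcript
from cerna_forge.lncrna_filter import (
    assign_class_codes,
    filter_lncrna,
    longest_orf,
    structural_stats,
)


def ann(*txs):
    out = AnnotationSet()
    for t in txs:
        out.add(t)
    return out


@pytest.fixture()
def reference():
    return ann(
        Transcript("ref1", "gA", "chr1", "+", [(1000, 1200), (1500, 1800), (2100, 2400)]),
        Transcript("ref2", "gB", "chr1", "-", [(5000, 5400)]),
        Transcript("ref3", "gC", "chr2", "+", [(100, 300), (600, 900)]),
    )


class TestClassCodes:
    def test_identical_exon_chain_is_equals(self, reference):
        cand = ann(
            Transcript("c", "c", "chr1", "+", [(1000, 1200), (1500, 1800), (2100, 2400)])
        )
        assert assign_class_codes(cand, reference)["c"] == "="

    def test_shared_junction_is_j(self, reference):
        cand = ann(Transcript("c", "c", "chr1", "+", [(1100, 1200), (1500, 1700)]))
        assert assign_class_codes(cand, reference)["c"] == "j"

    def test_same_strand_exonic_overlap_is_o(self, reference):
        cand = ann(Transcript("c", "c", "chr1", "+", [(1150, 1350)]))
        assert assign_class_codes(cand, reference)["c"] == "o"

    def test_intronic_same_strand_is_i(self, reference):
        cand = ann(Transcript("c", "c", "chr1", "+", [(1250, 1450)]))
        assert assign_class_codes(cand, reference)["c"] == "i"

    def test_antisense_exonic_overlap_is_x(self, reference):
        cand = ann(Transcript("c", "c", "chr1", "+", [(5100, 5300)]))
        assert assign_class_codes(cand, reference)["c"] == "x"

    def test_intergenic_is_u(self, reference):
        cand = ann(Transcript("c", "c", "chr1", "+", [(9000, 9400)]))
        assert assign_class_codes(cand, reference)["c"] == "u"

    def test_unknown_chromosome_is_u_with_warning(self, reference, caplog):
        cand = ann(Transcript("c", "c", "chrZ", "+", [(0, 100)]))
        assert assign_class_codes(cand, reference)["c"] == "u"

    def test_agrees_with_naive_oracle_on_random_placements(self, rng, reference):
        refs = list(reference)
        cands = AnnotationSet()
        for n in range(120):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, 6000))
            if rng.random() < 0.3:
                exons = [(start, start + int(rng.integers(50, 600)))]
            else:
                e1 = (start, start + int(rng.integers(50, 200)))
                gap = int(rng.integers(50, 400))
                e2 = (e1[1] + gap, e1[1] + gap + int(rng.integers(50, 200)))
                exons = [e1, e2]
            cands.add(Transcript(f"r{n}", f"r{n}", chrom, strand, exons))
        got = assign_class_codes(cands, reference)
        for cand in cands:
            assert got[cand.transcript_id] == oracles.naive_class_code(cand, refs), (
                cand.transcript_id, cand.exons, cand.strand,
            )


class TestFilter:
    def coding_table(self, ids, cnci=-3.0, cpc=-0.5):
        return pd.DataFrame(
            {"cnci_like": cnci, "cpc_like": cpc}, index=pd.Index(ids)
        )

    def test_short_candidate_removed_at_length_step(self):
        cands = ann(
            Transcript("short", "s", "chr1", "+", [(0, 150)]),
            Transcript("ok", "o", "chr1", "+", [(1000, 1250)]),
        )
        codes = {"short": "u", "ok": "u"}
        retained, audit = filter_lncrna(cands, codes, self.coding_table(["short", "ok"]))
        assert retained == ["ok"]
        assert audit.removed_length == 1

    def test_equals_code_removed_at_overlap_step(self):
        cands = ann(
            Transcript("eq", "e", "chr1", "+", [(0, 300)]),
            Transcript("ok", "o", "chr1", "+", [(1000, 1300)]),
        )
        retained, audit = filter_lncrna(
            cands, {"eq": "=", "ok": "x"}, self.coding_table(["eq", "ok"])
        )
        assert retained == ["ok"]
        assert audit.removed_class_code == 1

    def test_retained_candidate_passes_all_steps(self):
        cands = ann(Transcript("lnc", "l", "chr1", "+", [(0, 250)]))
        retained, audit = filter_lncrna(cands, {"lnc": "u"}, self.coding_table(["lnc"]))
        assert retained == ["lnc"]
        assert audit.n_retained == 1

    def test_literal_convention_deletes_doubly_negative_scores(self):
        cands = ann(Transcript("lnc", "l", "chr1", "+", [(0, 250)]))
        coding = self.coding_table(["lnc"], cnci=-3.0, cpc=-2.0)
        retained, audit = filter_lncrna(cands, {"lnc": "u"}, coding, convention="literal")
        assert retained == [] and audit.removed_coding_potential == 1
        retained, _ = filter_lncrna(cands, {"lnc": "u"}, coding, convention="standard")
        assert retained == ["lnc"]

    def test_standard_convention_deletes_coding_like_scores(self):
        cands = ann(Transcript("cod", "c", "chr1", "+", [(0, 400)]))
        coding = self.coding_table(["cod"], cnci=2.0, cpc=1.0)
        retained, _ = filter_lncrna(cands, {"cod": "u"}, coding, convention="standard")
        assert retained == []
        # the literal predicate keeps positive scores (faithfulness first)
        retained, _ = filter_lncrna(cands, {"cod": "u"}, coding, convention="literal")
        assert retained == ["cod"]

    def test_missing_scores_policy(self, caplog):
        cands = ann(Transcript("nos", "n", "chr1", "+", [(0, 250)]))
        empty = self.coding_table([])
        retained, audit = filter_lncrna(cands, {"nos": "u"}, empty, missing="drop")
        assert retained == [] and audit.removed_missing_scores == 1
        retained, _ = filter_lncrna(cands, {"nos": "u"}, empty, missing="pass")
        assert retained == ["nos"]

    def test_audit_counts_sum_to_input(self, small_scenario):
        sc = small_scenario
        codes = assign_class_codes(sc.candidates, sc.reference)
        retained, audit = filter_lncrna(
            sc.candidates, codes, sc.coding, convention="standard"
        )
        removed = (
            audit.removed_length
            + audit.removed_class_code
            + audit.removed_coding_potential
            + audit.removed_missing_scores
        )
        assert audit.n_input == removed + audit.n_retained
        assert set(retained) == {
            n for n, c in sc.ncrna_classes.items() if c == "lncRNA"
        }


class TestOrfAndStats:
    def test_no_atg_means_no_orf(self):
        assert longest_orf("CCCCCCGGGGGG") == 0

    def test_orf_requires_in_frame_stop(self):
        assert longest_orf("ATGAAACCC") == 0
        assert longest_orf("ATGAAATAA") == 9

    def test_longest_forward_orf_found_across_frames(self):
        # frame 1: ATG AAA TAA (9); frame 2 hosts a longer one
        seq = "ATGAAATAA" + "G" + "ATG" + "GCC" * 10 + "TGA"
        assert longest_orf(seq) == 36

    def test_planted_orf_lengths_recovered_in_histogram(self, rng):
        ann_set = AnnotationSet()
        seqs = SequenceSet(alphabet="dna")
        orf_lens = [30, 150, 330]
        for i, n_codons in enumerate([8, 48, 108]):
            tid = f"t{i}"
            body = "ATG" + "GCA" * n_codons + "TAA"
            seqs.add(tid, "CC" + body + "CC")
            ann_set.add(
                Transcript(tid, tid, "chr1", "+", [(0, len(body) + 4)])
            )
        stats = structural_stats([], ["t0", "t1", "t2"], ann_set, seqs)
        orf_rows = stats[(stats.statistic == "orf_length") & (stats.rna_class == "mRNA")]
        binned = dict(zip(orf_rows.bin, orf_rows["count"]))
        assert binned["[0,100)"] == 1      # 30 nt
        assert binned["[100,300)"] == 1    # 150 nt
        assert binned["[300,500)"] == 1    # 330 nt
        for want, (i, _) in zip(orf_lens, enumerate([8, 48, 108])):
            assert longest_orf(seqs[f"t{i}"]) == want

    def test_exon_count_distribution(self):
        ann_set = ann(
            Transcript("a", "a", "chr1", "+", [(0, 300)]),
            Transcript("b", "b", "chr1", "+", [(0, 100), (200, 300)]),
        )
        seqs = SequenceSet(alphabet="dna")
        seqs.add("a", "A" * 300)
        seqs.add("b", "A" * 200)
        stats = structural_stats(["a", "b"], [], ann_set, seqs)
        rows = stats[(stats.statistic == "exon_count") & (stats.rna_class == "lncRNA")]
        assert dict(zip(rows.bin, rows["count"])) == {"1": 1, "2": 1}
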