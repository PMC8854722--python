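import numpy as np
import pytest

import oracles
from conftest import random_dna, random_rna, seqset
from cerna_forge.target_scoring import (
    MIRNA_GAP,
    ScoringScheme,
    align_site,
    predict_targets,
    score_duplex,
)
from cerna_forge.synthetic_data import compose_penalty, plant_duplex

RC = {"A": "U", "C": "G", "G": "C", "U": "A"}


def revcomp(seq):
    return "".join(RC[c] for c in reversed(seq))


def gu_substituted(mirna, window, pos):
    """Turn the pair at miRNA position `pos` into a G:U wobble."""
    out = list(window)
    idx = len(window) - pos
    out[idx] = {"G": "U", "U": "G"}[mirna[pos - 1]]
    return "".join(out)


def mismatched(mirna, window, pos):
    out = list(window)
    idx = len(window) - pos
    nt = mirna[pos - 1]
    out[idx] = next(
        c for c in "ACGU" if c != RC[nt] and (nt, c) not in (("G", "U"), ("U", "G"))
    )
    return "".join(out)


@pytest.fixture()
def mirna():
    # fixed 21-mer with G/U available at positions 5 and 18
    return "UGACGGUAUCGAAGCUCGAAU"


class TestScoreDuplex:
    def test_perfect_duplex_scores_zero(self, mirna):
        aln = score_duplex(mirna, revcomp(mirna), ScoringScheme(), "|" * 21)
        assert aln.score == 0.0
        assert aln.breakdown == {}

    def test_wobble_outside_core_costs_half_point(self, mirna):
        window = gu_substituted(mirna, revcomp(mirna), 18)
        aln = align_site(mirna, window)
        assert aln.score == 0.5

    def test_wobble_inside_core_costs_double(self, mirna):
        window = gu_substituted(mirna, revcomp(mirna), 5)
        assert align_site(mirna, window).score == 1.0

    def test_mismatch_costs_one_point(self, mirna):
        window = mismatched(mirna, revcomp(mirna), 20)
        assert align_site(mirna, window).score == 1.0

    def test_core_multiplier_configurable_to_gu_only(self, mirna):
        scheme = ScoringScheme(core_applies_to="gu_only")
        mm_core = mismatched(mirna, revcomp(mirna), 5)
        gu_core = gu_substituted(mirna, revcomp(mirna), 5)
        assert align_site(mirna, mm_core, scheme).score == 1.0
        assert align_site(mirna, gu_core, scheme).score == 1.0

    def test_inconsistent_path_state_rejected(self, mirna):
        with pytest.raises(ValueError, match="disagrees"):
            score_duplex(mirna, mismatched(mirna, revcomp(mirna), 3),
                         ScoringScheme(), "|" * 21)

    def test_incomplete_path_rejected(self, mirna):
        with pytest.raises(ValueError, match="consumed"):
            score_duplex(mirna, revcomp(mirna), ScoringScheme(), "|" * 20)


class TestAlignSite:
    def test_reverse_complement_gives_all_wc(self, mirna):
        aln = align_site(mirna, revcomp(mirna))
        assert aln.score == 0.0 and aln.pairing == "|" * 21

    def test_window_one_short_forces_single_mirna_gap(self, rng):
        for _ in range(10):
            mir = random_rna(rng, 21)
            window = revcomp(mir)
            cut = int(rng.integers(0, len(window)))
            short = window[:cut] + window[cut + 1 :]
            aln = align_site(mir, short)
            assert aln.pairing.count(MIRNA_GAP) == 1
            oracle_score, _ = oracles.best_alignment(mir, short, ScoringScheme(), 2)
            assert aln.score == pytest.approx(oracle_score, abs=1e-9)

    def test_negative_max_gaps_rejected(self, mirna):
        with pytest.raises(ValueError, match="max_gaps"):
            align_site(mirna, revcomp(mirna), max_gaps=-1)

    def test_incompatible_window_length_rejected(self, mirna):
        with pytest.raises(ValueError, match="incompatible"):
            align_site(mirna, revcomp(mirna)[:10])

    def test_matches_exhaustive_enumeration(self, rng):
        """DP equals brute-force path enumeration, including tie-breaks."""
        scheme = ScoringScheme()
        for _ in range(60):
            m = int(rng.integers(12, 22))
            mir = random_rna(rng, m)
            base = list(revcomp(mir))
            for _ in range(int(rng.integers(0, 7))):
                base[int(rng.integers(0, len(base)))] = random_rna(rng, 1)
            for _ in range(int(rng.integers(0, 3))):
                if rng.random() < 0.5 and len(base) > m - 2:
                    del base[int(rng.integers(0, len(base)))]
                elif len(base) < m + 2:
                    base.insert(int(rng.integers(0, len(base) + 1)), random_rna(rng, 1))
            window = "".join(base)
            if not (m - 2 <= len(window) <= m + 2):
                continue
            got = align_site(mir, window, scheme, 2)
            score, pairing = oracles.best_alignment(mir, window, scheme, 2)
            assert got.score == pytest.approx(score, abs=1e-9)
            assert got.pairing == pairing


class TestScoringProperties:
    def test_mismatch_never_cheaper_than_wc(self, rng):
        """Replacing a WC pair with a mismatch never decreases the score."""
        for _ in range(20):
            mir = random_rna(rng, 18)
            window = revcomp(mir)
            before = align_site(mir, window).score
            pos = int(rng.integers(1, 19))
            after = align_site(mir, mismatched(mir, window, pos)).score
            assert after >= before

    def test_core_penalty_dominates_outside(self, rng):
        """Moving one G:U or mismatch into the core never lowers the score."""
        scheme = ScoringScheme()
        for _ in range(20):
            mir = random_rna(rng, 21)
            window = revcomp(mir)
            outside = [p for p in (1, 14, 21) if mir[p - 1] in "GU"]
            inside = [p for p in range(2, 14) if mir[p - 1] in "GU"]
            if outside and inside:
                s_out = align_site(mir, gu_substituted(mir, window, outside[0]), scheme)
                s_in = align_site(mir, gu_substituted(mir, window, inside[0]), scheme)
                assert s_in.score >= s_out.score
            s_out = align_site(mir, mismatched(mir, window, 14), scheme)
            s_in = align_site(mir, mismatched(mir, window, 7), scheme)
            assert s_in.score >= s_out.score


class TestPredictTargets:
    def test_planted_perfect_site_is_found_exactly(self, rng):
        mir = random_rna(rng, 21)
        window = revcomp(mir).replace("U", "T")
        seq = random_dna(rng, 60) + window + random_dna(rng, 60)
        sites = predict_targets(
            seqset("rna", m1=mir), seqset("dna", t1=seq)
        )
        hit = [s for s in sites if s.target_window == (60, 81)]
        assert hit and hit[0].score == 0.0

    def test_sites_above_cutoff_are_not_reported(self, rng):
        """A planted 4.5-point site exceeds the 4-point retention cutoff."""
        scheme = ScoringScheme()
        mir = "UGACGGUAUCGAAGCUCGAAU"
        comp = compose_penalty(mir, 4.5, rng, scheme)
        window, _ = plant_duplex(mir, comp, rng, scheme)
        seq = random_dna(rng, 50) + window.replace("U", "T") + random_dna(rng, 50)
        sites = predict_targets(seqset("rna", m1=mir), seqset("dna", t1=seq))
        assert all(s.score <= 4.0 for s in sites)

    def test_retained_set_straddling_cutoff_matches_plan(self, small_scenario):
        """Every planted site <= 4 points is reported at its planted penalty
        and window; every planted decoy > 4 points is absent."""
        sc = small_scenario
        sites = predict_targets(sc.mirnas, sc.mrna_seqs)
        got = {(s.mirna_id, s.target_id, *s.target_window, s.score) for s in sites}
        truth = sc.truth_target_sites
        want = {
            (r.mirna_id, r.target_id, r.start, r.end, float(r.penalty))
            for r in truth[truth.penalty <= 4.0].itertuples()
        }
        assert got == want

    def test_short_transcript_skipped(self, rng, caplog):
        mir = random_rna(rng, 21)
        sites = predict_targets(
            seqset("rna", m1=mir), seqset("dna", t1="ACGTACGT")
        )
        assert sites == []

    def test_empty_input_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            predict_targets(seqset("rna"), seqset("dna", t1="ACGT" * 10))
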