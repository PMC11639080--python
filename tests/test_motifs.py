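"""Motif scanners against constructed fixtures and naive oracles."""

import random

import pytest

from satfold.motifs import (
    MotifConfig,
    MotifHit,
    PalindromeParams,
    dyad_density,
    find_palindromes,
    motif_occupancy,
    scan_non_b_motifs,
)
from satfold.sequence import revcomp
from conftest import random_dna
from oracles import naive_two_arm


def _screened_background(rng, n):
    """Background with no dyad hit, screened by the scanner itself.

    Drawn over {A, C}: no complementary pair exists inside that
    alphabet, so the background is palindrome-free by construction
    (the test still asserts the scan finds nothing extra).
    """
    seq = random_dna(rng, n, alphabet="AC")
    assert find_palindromes(seq) == []
    return seq


class TestFindPalindromes:
    def test_homopolymer_has_no_hits(self):
        assert find_palindromes("A" * 100) == []

    def test_constructed_arm8_spacer4(self):
        arm = "GGGCCTTA"
        seq = "T" + arm + "AAAA" + revcomp(arm) + "G"
        hits = find_palindromes(seq, PalindromeParams())
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.arm_length, h.spacer_length) == (1, 21, 8, 4)
        # the naive all-pairs scanner agrees
        assert naive_two_arm(seq, 5, 100, 20, mirror=False) == \
            [(h.start, h.end, h.arm_length, h.spacer_length)]

    def test_two_embedded_palindromes_recovered(self):
        rng = random.Random(42)
        bg = _screened_background(rng, 1000)
        arm1, arm2 = "GTCCA", "TAGGC"
        ins1 = arm1 + "AT" + revcomp(arm1)
        ins2 = arm2 + "CG" + revcomp(arm2)
        seq = bg[:300] + ins1 + bg[300:700] + ins2 + bg[700:]
        hits = find_palindromes(seq, PalindromeParams())
        spans = {(h.start, h.end) for h in hits}
        assert (300, 300 + len(ins1)) in spans
        assert (300 + len(ins1) + 400, 300 + len(ins1) + 400 + len(ins2)) in spans
        assert len(hits) == 2

    def test_min_arm_below_two_rejected(self):
        with pytest.raises(ValueError, match="min_arm"):
            PalindromeParams(min_arm=1)

    def test_hit_symmetry_under_revcomp(self):
        rng = random.Random(5)
        seq = random_dna(rng, 800)
        fwd = find_palindromes(seq)
        rev = find_palindromes(revcomp(seq))
        n = len(seq)
        mirrored = sorted((n - h.end, n - h.start, h.arm_length, h.spacer_length)
                          for h in rev)
        assert sorted((h.start, h.end, h.arm_length, h.spacer_length)
                      for h in fwd) == mirrored

    def test_dyad_density_revcomp_invariant(self):
        rng = random.Random(6)
        seq = random_dna(rng, 1500)
        d1 = dyad_density(len(seq), find_palindromes(seq))
        d2 = dyad_density(len(seq), find_palindromes(revcomp(seq)))
        assert d1 == pytest.approx(d2)


class TestDyadDensity:
    def test_no_hits_zero(self):
        assert dyad_density(100, []) == 0.0

    def test_single_arm10_hit_in_100nt(self):
        h = MotifHit("palindrome", 0, 25, arm_length=10, spacer_length=5)
        assert dyad_density(100, [h]) == pytest.approx(0.20)

    def test_two_arm5_hits_in_200nt(self):
        hits = [MotifHit("palindrome", 0, 10, arm_length=5),
                MotifHit("palindrome", 100, 110, arm_length=5)]
        assert dyad_density(200, hits) == pytest.approx(0.10)

    def test_bad_length(self):
        with pytest.raises(ValueError):
            dyad_density(0, [])

    def test_density_above_one_warns_but_reports(self):
        hits = [MotifHit("palindrome", 0, 50, arm_length=25)] * 3
        with pytest.warns(UserWarning, match="exceeds 1"):
            assert dyad_density(100, hits) == pytest.approx(1.5)


class TestNonBScanners:
    def test_mirror_repeat_with_two_nt_spacer(self):
        # arm 8 + spacer 2 + reversed arm; scanned with an arm-8 config
        hits = scan_non_b_motifs("ATCTCGGCACCGGCTCTA",
                                 MotifConfig(mirror_min_arm=8))["mirror_repeat"]
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.arm_length, h.spacer_length) == (0, 18, 8, 2)

    def test_g4_spans_full_canonical_motif(self):
        hits = scan_non_b_motifs("GGGAGGGAGGGAGGG")["g4"]
        assert [(h.start, h.end) for h in hits] == [(0, 15)]

    def test_g4_linker_too_long_breaks_chain(self):
        seq = "GGG" + "A" * 8 + "GGGAGGGAGGG"
        assert scan_non_b_motifs(seq)["g4"] == []

    def test_poly_a_50(self):
        out = scan_non_b_motifs("A" * 50)
        assert out["z_dna"] == []
        assert out["g4"] == []
        assert out["inverted_repeat"] == []
        assert out["a_phased"] == []       # one 50-nt run is not a 3-9 nt tract
        assert out["mirror_repeat"] == []  # homopolymer arms suppressed
        assert [(h.start, h.end, h.unit) for h in out["str"]] == [(0, 50, "A")]

    def test_z_dna_alternating_tract(self):
        # T.G and C.A steps alternate too, so the tract spans 1..27
        hits = scan_non_b_motifs("TT" + "GC" * 12 + "AA")["z_dna"]
        assert [(h.start, h.end) for h in hits] == [(1, 27)]
        assert scan_non_b_motifs("GC" * 9)["z_dna"] == []  # 9 dinucleotides < 10

    def test_a_phased_three_tracts(self):
        seq = ("AAAAA" + "GCGCG") * 3
        hits = scan_non_b_motifs(seq)["a_phased"]
        assert [(h.start, h.end) for h in hits] == [(0, 25)]

    def test_direct_repeat_with_spacer(self):
        u = "ACGTACGTGG"
        seq = "TTT" + u + "CC" + u + "TTT"
        hits = scan_non_b_motifs(seq)["direct_repeat"]
        assert [(h.start, h.end, h.arm_length, h.spacer_length, h.unit)
                for h in hits] == [(3, 25, 10, 2, u)]

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            scan_non_b_motifs("ACGT" * 10, classes=("h_dna",))


class TestMotifOccupancy:
    def test_empty_hits_all_zero(self):
        occ = motif_occupancy({"g4": [], "z_dna": []}, 1000)
        assert occ == {"g4": 0.0, "z_dna": 0.0}

    def test_single_40nt_inverted_repeat_in_1kb(self):
        hits = {"inverted_repeat": [MotifHit("inverted_repeat", 100, 140,
                                             arm_length=18, spacer_length=4)]}
        assert motif_occupancy(hits, 1000)["inverted_repeat"] == pytest.approx(0.04)

    def test_bad_total_length(self):
        with pytest.raises(ValueError):
            motif_occupancy({}, 0)
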