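"""Synthetic genome generator: determinism, parameter fidelity, truth
round trips."""

import numpy as np
import pytest

from satfold.motifs import PalindromeParams, dyad_density, find_palindromes
from satfold.sampling import check_eligibility, load_region_annotation
from satfold.sequence import revcomp
from satfold.stats import gc_content
from satfold.synth import (
    SyntheticRegionSpec,
    build_fixture_genome,
    insert_dyads,
    make_hor_array,
    default_gradients_preset,
)


class TestHorArray:
    def test_zero_divergence_copies_identical(self):
        spec = SyntheticRegionSpec("active_hor", monomer_length=50,
                                   monomers_per_hor=4, n_hor_units=6, seed=3)
        arr = make_hor_array(spec)
        unit_len = 200
        units = [arr[i:i + unit_len] for i in range(0, len(arr), unit_len)]
        assert len(set(units)) == 1

    def test_divergence_matches_binomial_expectation(self):
        rate = 0.05
        spec = SyntheticRegionSpec("active_hor", monomer_length=171,
                                   monomers_per_hor=4, n_hor_units=15,
                                   divergence_rate=rate, seed=11)
        ref = make_hor_array(SyntheticRegionSpec(
            "active_hor", monomer_length=171, monomers_per_hor=4,
            n_hor_units=1, seed=spec.seed))
        arr = make_hor_array(spec)
        L = len(ref)
        diffs = [sum(a != b for a, b in zip(arr[i * L:(i + 1) * L], ref))
                 for i in range(15)]
        mean = np.mean(diffs)
        sd = np.sqrt(L * rate * (1 - rate))
        assert abs(mean - L * rate) < 3 * sd

    def test_gc_within_two_percent_of_target(self):
        spec = SyntheticRegionSpec("active_hor", gc_target=0.60,
                                   monomers_per_hor=12, n_hor_units=10, seed=5)
        arr = make_hor_array(spec)
        assert len(arr) >= 20_000
        assert abs(gc_content(arr) - 0.60) <= 0.02

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticRegionSpec("active_hor", gc_target=1.2)
        with pytest.raises(ValueError):
            SyntheticRegionSpec("active_hor", divergence_rate=1.0)
        with pytest.raises(ValueError):
            SyntheticRegionSpec("active_hor", monomer_length=5)


class TestInsertDyads:
    def test_count_zero_noop(self):
        seq = "ACGT" * 100
        out, truth = insert_dyads(seq, 10, 5, 0, seed=1)
        assert out == seq and truth == []

    def test_insertions_recovered_at_truth_coordinates(self):
        rng = np.random.default_rng(2)
        base = "".join(np.array(list("AC"))[rng.integers(0, 2, 10_000)])
        out, truth = insert_dyads(base, 10, 5, 3, seed=9)
        hits = find_palindromes(out, PalindromeParams(min_arm=10, gap_limit=5))
        spans = {(h.start, h.end) for h in hits}
        assert len(truth) == 3
        for start, end, arm, spacer in truth:
            assert (start, end) in spans

    def test_recovery_survives_revcomp(self):
        rng = np.random.default_rng(3)
        base = "".join(np.array(list("AC"))[rng.integers(0, 2, 10_000)])
        out, truth = insert_dyads(base, 10, 5, 3, seed=10)
        hits = find_palindromes(revcomp(out), PalindromeParams(min_arm=10, gap_limit=5))
        n = len(out)
        spans = {(n - h.end, n - h.start) for h in hits}
        for start, end, *_ in truth:
            assert (start, end) in spans

    def test_insufficient_room(self):
        with pytest.raises(ValueError, match="room"):
            insert_dyads("ACGT" * 10, 10, 5, 10, seed=0)


@pytest.fixture(scope="module")
def genome():
    return build_fixture_genome(default_gradients_preset(2), seed=2)


class TestFixtureGenome:
    def test_same_seed_identical_fasta_bytes(self, genome, tmp_path):
        g2 = build_fixture_genome(default_gradients_preset(2), seed=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1, p2 = genome.write(d1), g2.write(d2)
        assert p1["fasta"].read_bytes() == p2["fasta"].read_bytes()
        assert p1["bed"].read_bytes() == p2["bed"].read_bytes()

    def test_designed_exclusions_at_4kb(self, genome):
        status = {}
        for chrom in genome.sequences:
            ivs = [iv for iv in genome.intervals if iv.chrom == chrom]
            status[chrom] = check_eligibility(ivs, "divergent_hor", 4000)
        excluded = {c for c, e in status.items() if not e.eligible}
        assert excluded == {"chrS7", "chrS8"}
        assert status["chrS7"].reason == "region absent"
        assert status["chrS8"].reason == "span < window"
        # both are eligible (or absent) as designed at 1 kb
        ivs8 = [iv for iv in genome.intervals if iv.chrom == "chrS8"]
        assert check_eligibility(ivs8, "divergent_hor", 1000).eligible

    def test_gc_gradient_encoded(self, genome):
        by_region = {}
        for _, row in genome.region_truth.iterrows():
            seq = genome[row.chrom][row.start:row.end]
            by_region.setdefault(row.region_label, []).append(gc_content(seq))
        means = {r: np.mean(v) for r, v in by_region.items()}
        assert means["centric_transition"] > means["active_hor"] > means["divergent_hor"]
        assert means["rdna"] > means["coding"] > means["centric_transition"]

    def test_dyad_gradient_encoded(self, genome):
        counts = (
            genome.repeat_truth[genome.repeat_truth.kind == "inverted"]
            .groupby("region_label").size()
        )
        assert counts["centric_transition"] > counts["divergent_hor"] > counts["active_hor"]

    def test_measured_dyad_density_gradient(self, genome):
        """The insertion gradient dominates the background dyad level,
        so the scanned (not just designed) density is ordered."""
        means = {}
        for region in ("active_hor", "divergent_hor", "centric_transition"):
            dds = []
            for chrom in genome.sequences:
                seqs = [genome[iv.chrom][iv.start:iv.end]
                        for iv in genome.intervals
                        if iv.chrom == chrom and iv.region_label == region]
                if seqs:
                    whole = "".join(seqs)
                    dds.append(dyad_density(len(whole), find_palindromes(whole)))
            means[region] = np.mean(dds)
        assert means["centric_transition"] > means["divergent_hor"] > means["active_hor"]

    def test_annotation_round_trip(self, genome, tmp_path):
        paths = genome.write(tmp_path / "g")
        loaded = load_region_annotation(paths["bed"])
        assert [(iv.chrom, iv.start, iv.end, iv.region_label) for iv in loaded] == \
            [(iv.chrom, iv.start, iv.end, iv.region_label) for iv in genome.intervals]

    def test_missegregation_probabilities_valid(self, genome):
        assert ((genome.missegregation >= 0) & (genome.missegregation <= 1)).all()
        assert set(genome.missegregation.index) == set(genome.sequences)
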