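"""Microsatellite, dispersed-repeat, and tandem-repeat detection."""

import numpy as np
import pytest

import oracles
from conftest import random_dna
from plastokit._genetics import minimal_rotation, revcomp
from plastokit.genome_io import GeneAnnotation, RegionPartition
from plastokit.repeat_scan import (
    DEFAULT_SSR_THRESHOLDS,
    SSRRecord,
    find_dispersed,
    find_ssrs,
    find_tandem,
    localize,
    merge_compound,
)


class TestSSRs:
    def test_mononucleotide_at_threshold(self):
        recs = find_ssrs("G" + "A" * 10 + "G")
        assert len(recs) == 1
        r = recs[0]
        assert (r.motif, r.copies, r.start, r.end) == ("A", 10, 1, 11)

    def test_below_threshold_not_reported(self):
        assert find_ssrs("A" * 9) == []

    def test_dinucleotide_reported_at_smallest_period_only(self):
        recs = find_ssrs("ATATATATAT")
        assert len(recs) == 1
        assert (recs[0].motif, recs[0].copies) == ("AT", 5)
        # oracle: exhaustive all-period scan agrees
        oracle = oracles.brute_force_ssrs("ATATATATAT", DEFAULT_SSR_THRESHOLDS)
        assert {(r.start, r.unit_len, r.copies) for r in recs} == oracle

    def test_poly_a_never_reported_as_dinucleotide(self):
        recs = find_ssrs("C" + "A" * 12 + "C")
        assert [(r.motif, r.unit_len, r.copies) for r in recs] == [("A", 1, 12)]

    def test_n_breaks_runs(self):
        assert find_ssrs("A" * 6 + "N" + "A" * 6) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 5000, gc=0.3)
        got = {(r.start, r.unit_len, r.copies) for r in find_ssrs(seq)}
        assert got == oracles.brute_force_ssrs(seq, DEFAULT_SSR_THRESHOLDS)

    def test_strand_symmetry_of_motif_multiset(self, rng):
        seq = random_dna(rng, 4000, gc=0.25) + "A" * 11 + random_dna(rng, 200, gc=0.25)
        fwd = sorted(
            (minimal_rotation(revcomp(r.motif)), r.copies) for r in find_ssrs(seq)
        )
        rev = sorted((r.motif, r.copies) for r in find_ssrs(revcomp(seq)))
        assert fwd == rev

    def test_maximality_cannot_extend_by_one_unit(self, rng):
        seq = random_dna(rng, 5000, gc=0.5)
        for r in find_ssrs(seq):
            unit = seq[r.start : r.start + r.unit_len]
            left = seq[r.start - r.unit_len : r.start]
            right_end = r.start + (r.copies + 1) * r.unit_len
            right = seq[r.start + r.copies * r.unit_len : right_end]
            assert left != unit
            assert right != unit


class TestCompound:
    def _ssr(self, start, end):
        return SSRRecord("A", 1, end - start, start, end)

    @pytest.mark.parametrize(
        "gap,same", [(50, True), (100, True), (101, False)]
    )
    def test_gap_rule_boundary(self, gap, same):
        a = self._ssr(0, 100)
        b = self._ssr(100 + gap, 120 + gap)
        out = merge_compound([a, b], max_gap=100)
        if same:
            assert out[0].compound_id is not None
            assert out[0].compound_id == out[1].compound_id
        else:
            assert out[0].compound_id is None and out[1].compound_id is None

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            merge_compound([self._ssr(100, 110), self._ssr(0, 10)])


class TestDispersed:
    def test_planted_forward_pair(self, rng):
        seq = list(random_dna(rng, 8000, gc=0.5))
        block = random_dna(rng, 40, gc=0.5)
        seq[1000:1040] = block
        seq[5000:5040] = block
        hits = [r for r in find_dispersed("".join(seq)) if r.kind == "F"]
        # maximal windows absorb flank mismatches up to the budget, so the
        # reported repeat contains the planted block
        containing = [
            r for r in hits
            if r.pos1 <= 1000 and r.pos1 + r.length >= 1040 and r.pos2 <= 5000
        ]
        assert containing
        assert all(r.length >= 40 for r in containing)

    def test_planted_palindromic_pair(self, rng):
        seq = list(random_dna(rng, 8000, gc=0.5))
        block = random_dna(rng, 40, gc=0.5)
        seq[1000:1040] = block
        seq[5000:5040] = revcomp(block)
        hits = [r for r in find_dispersed("".join(seq)) if r.kind == "P"]
        assert any(r.pos1 <= 1000 and r.pos2 <= 5000 and r.length >= 40 for r in hits)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = list(random_dna(rng, 1200, gc=0.5))
        # plant one pair of each kind so the comparison is not vacuous
        block = random_dna(rng, 34, gc=0.5)
        seq[50:84] = block
        seq[300:334] = block
        seq[600:634] = revcomp(block)
        seq[900:934] = block[::-1]
        s = "".join(seq)
        got = {
            (r.kind, r.pos1, r.pos2, r.length)
            for r in find_dispersed(s, min_len=30, max_mismatch=3)
            if r.length <= 60
        }
        expected = oracles.brute_force_dispersed(s, min_len=30, max_len=60, max_mismatch=3)
        assert got == expected


class TestTandem:
    def test_exact_planted_array(self, rng):
        unit = "ACGTTGAC"  # primitive 8-mer
        seq = "CC" + random_dna(rng, 500, gc=0.5) + unit * 4 + random_dna(rng, 500, gc=0.5)
        hits = [t for t in find_tandem(seq) if t.start <= 502 + len(unit) and t.end >= 502 + 32]
        assert hits
        best = hits[0]
        assert best.copies >= 4
        assert best.identity == 1.0

    def test_single_substitution_identity(self):
        unit = "ACGTTGACTAGCATG"  # 15 bp primitive unit
        arr = list(unit * 3)
        arr[20] = "A" if arr[20] != "A" else "C"
        # flanks chosen not to extend the array period by chance
        seq = "CC" + "".join(arr) + "TT"
        hits = find_tandem(seq)
        assert hits
        t = hits[0]
        assert abs(t.identity - (1 - 1 / (3 * 15))) < 1e-9

    def test_homopolymer_left_to_ssr_module(self):
        assert find_tandem("A" * 40) == []

    def test_low_period_array_left_to_ssr_module(self, rng):
        seq = random_dna(rng, 300, gc=0.5) + "ACGT" * 8 + random_dna(rng, 300, gc=0.5)
        for t in find_tandem(seq):
            assert not (t.start < 332 and t.end > 300)


class TestLocalize:
    def _setup(self):
        part = RegionPartition((0, 1000), (1000, 1500), (1500, 2000), (2000, 2500))
        genes = [GeneAnnotation("g1", "CDS", "+", [(100, 200), (300, 400)])]
        return part, genes

    def test_midpoint_in_exon_is_cds(self):
        part, genes = self._setup()
        f = SSRRecord("A", 1, 10, 150, 160)
        localize([f], part, genes, 2500)
        assert (f.region, f.context) == ("LSC", "CDS")

    def test_midpoint_between_exons_is_intron(self):
        part, genes = self._setup()
        f = SSRRecord("A", 1, 10, 250, 260)
        localize([f], part, genes, 2500)
        assert f.context == "intron"

    def test_between_genes_is_igs(self):
        part, genes = self._setup()
        f = SSRRecord("A", 1, 10, 600, 610)
        localize([f], part, genes, 2500)
        assert f.context == "IGS"

    def test_boundary_straddling_feature_uses_midpoint_region(self):
        part, genes = self._setup()
        f = SSRRecord("A", 1, 20, 990, 1010)  # midpoint 999 -> LSC
        localize([f], part, genes, 2500)
        assert f.region == "LSC"
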