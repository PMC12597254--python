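"""Sliding-window π, variability tiers, variant calling, and distances."""

import math

import numpy as np
import pytest

import oracles
from conftest import random_dna
from plastokit.diversity import (
    AlignmentMatrix,
    WindowDiversity,
    call_variants,
    classify_variability,
    genetic_distance,
    sliding_window_pi,
)


def _aln(*rows):
    return AlignmentMatrix.from_sequences(
        [(f"s{i}", r) for i, r in enumerate(rows)]
    )


class TestSlidingWindowPi:
    def test_identical_rows_give_zero_everywhere(self):
        aln = _aln("ACGT" * 200, "ACGT" * 200)
        assert all(w.pi == 0.0 for w in sliding_window_pi(aln))

    def test_two_rows_closed_form(self):
        a = list("A" * 100)
        b = list(a)
        for i in (10, 50, 90):
            b[i] = "C"
        aln = _aln("".join(a), "".join(b))
        wins = sliding_window_pi(aln, window=100, step=100)
        assert wins[0].pi == pytest.approx(0.03)

    def test_gap_columns_excluded_pairwise(self):
        aln = _aln("AAAA-AAAAA", "AAAACAAAAC")
        w = sliding_window_pi(aln, window=10, step=10)[0]
        # 9 comparable sites, 1 mismatch
        assert w.pi == pytest.approx(1 / 9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base = random_dna(rng, 1000, gc=0.4)
        rows = []
        for _ in range(4):
            r = list(base)
            for pos in rng.choice(1000, size=30, replace=False):
                r[pos] = "ACGT"[rng.integers(0, 4)]
            if rng.random() < 0.5:
                g = rng.integers(0, 990)
                r[g : g + 5] = "-" * 5
            rows.append("".join(r))
        aln = AlignmentMatrix.from_sequences([(f"t{i}", r) for i, r in enumerate(rows)])
        for w in sliding_window_pi(aln, window=300, step=150):
            expect = oracles.direct_pi(rows, w.start, w.end)
            assert w.pi == pytest.approx(expect, abs=1e-12)

    def test_pi_invariant_under_row_permutation(self, rng):
        rows = []
        base = random_dna(rng, 600)
        for _ in range(4):
            r = list(base)
            for pos in rng.choice(600, size=12, replace=False):
                r[pos] = "ACGT"[rng.integers(0, 4)]
            rows.append("".join(r))
        aln1 = AlignmentMatrix.from_sequences([(f"t{i}", r) for i, r in enumerate(rows)])
        aln2 = AlignmentMatrix.from_sequences(
            [(f"t{i}", r) for i, r in enumerate(rows[::-1])]
        )
        p1 = [w.pi for w in sliding_window_pi(aln1)]
        p2 = [w.pi for w in sliding_window_pi(aln2)]
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_final_partial_window_has_true_span(self):
        aln = _aln("A" * 700, "A" * 700)
        wins = sliding_window_pi(aln, window=600, step=200)
        assert wins[-1].end == 700
        assert wins[-1].end - wins[-1].start < 600


class TestVariability:
    def _win(self, pi):
        return WindowDiversity(0, 100, pi, 100)

    @pytest.mark.parametrize(
        "pi,var_class,hot",
        [
            (0.061, "high", True),
            (0.015, "medium", False),
            (0.0099, "low", False),
            (0.02, "medium", False),   # boundary: medium is 0.01..0.02 inclusive
            (0.01, "medium", False),
            (0.021, "high", False),
        ],
    )
    def test_tier_boundaries(self, pi, var_class, hot):
        wins, _ = classify_variability([self._win(pi)])
        assert wins[0].var_class == var_class
        assert wins[0].hotspot is hot

    def test_contiguous_hotspots_merge_and_get_named(self):
        wins = [
            WindowDiversity(0, 100, 0.005, 100),
            WindowDiversity(100, 200, 0.08, 100),
            WindowDiversity(200, 300, 0.07, 100),
            WindowDiversity(500, 600, 0.09, 100),
        ]
        ann = [(0, 90, "ndhF"), (320, 420, "rpl32"), (700, 800, "ccsA")]
        _, intervals = classify_variability(wins, annotations=ann)
        assert len(intervals) == 2
        assert intervals[0].start == 100 and intervals[0].end == 300
        assert intervals[0].name == "ndhF-rpl32"
        assert intervals[1].name == "rpl32-ccsA"


class TestVariants:
    def test_single_snv(self):
        aln = _aln("ACGTACGT", "ACGAACGT")
        vt = call_variants(aln, "s0")
        assert vt.bins["snv"].sum() == 1
        assert vt.bins["indel"].sum() == 0

    def test_gap_run_is_one_event(self):
        aln = _aln("ACGTACGTAA", "ACG---GTAA")
        vt = call_variants(aln, "s0")
        assert vt.bins["indel"].sum() == 1

    def test_missing_reference_raises(self):
        aln = _aln("ACGT", "ACGA")
        with pytest.raises(KeyError):
            call_variants(aln, "nope")

    def test_simulated_rates_recovered(self, rng):
        n = 20000
        ref = random_dna(rng, n)
        sample = list(ref)
        snv_pos = rng.choice(n, size=int(0.02 * n), replace=False)
        for p in snv_pos:
            old = sample[p]
            sample[p] = "ACGT"[("ACGT".index(old) + 1) % 4]
        # indels: plant as gap runs at spaced positions
        n_indel = int(0.002 * n / 4)
        for i in range(n_indel):
            p = 200 * i + 100
            sample[p : p + 3] = "---"
        aln = _aln(ref, "".join(sample))
        vt = call_variants(aln, "s0")
        snvs = vt.bins["snv"].sum()
        indels = vt.bins["indel"].sum()
        planted_snv_remaining = sum(
            1 for p in snv_pos if sample[p] not in ("-",) and ref[p] != sample[p]
        )
        assert abs(snvs - planted_snv_remaining) <= 0.1 * planted_snv_remaining
        assert abs(indels - n_indel) <= max(1, 0.1 * n_indel)


class TestTierExport:
    def test_genes_binned_by_pi_and_concatenated(self, tmp_path, rng):
        from plastokit.diversity import export_tier_fastas

        def mutated(base, k):
            r = list(base)
            for pos in rng.choice(len(base), size=k, replace=False):
                r[pos] = "ACGT"[rng.integers(0, 4)]
            return "".join(r)

        alns = {}
        pis = {}
        for gene, k in (("hi", 40), ("mid", 12), ("lo", 0)):
            base = random_dna(rng, 600)
            aln = AlignmentMatrix.from_sequences(
                [("a", base), ("b", mutated(base, k))]
            )
            alns[gene] = aln
            pis[gene] = sliding_window_pi(aln, window=600, step=600)[0].pi
        paths = export_tier_fastas(alns, pis, tmp_path)
        assert set(paths) == {"high", "medium", "low"}
        text = paths["high"].read_text()
        assert text.startswith(">a\n") and len(text.splitlines()[1]) == 600


class TestDistances:
    def test_identical_rows_give_zero(self):
        aln = _aln("ACGT" * 50, "ACGT" * 50)
        for model in ("p", "K2P"):
            assert genetic_distance(aln, model).values[0, 1] == 0.0

    def test_p_distance_closed_form(self):
        a = list("A" * 100)
        b = list(a)
        for i in (3, 33, 66):
            b[i] = "G"
        aln = _aln("".join(a), "".join(b))
        assert genetic_distance(aln, "p").values[0, 1] == pytest.approx(0.03)

    def test_k2p_closed_form(self):
        # 100 sites: 5 transitions (A->G), 2 transversions (A->C)
        a = ["A"] * 100
        b = list(a)
        for i in range(5):
            b[i] = "G"
        for i in range(5, 7):
            b[i] = "C"
        aln = _aln("".join(a), "".join(b))
        P, Q = 0.05, 0.02
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert genetic_distance(aln, "K2P").values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_k2p_at_least_p_distance(self, rng):
        rows = []
        base = random_dna(rng, 2000)
        for _ in range(4):
            r = list(base)
            for pos in rng.choice(2000, size=100, replace=False):
                r[pos] = "ACGT"[rng.integers(0, 4)]
            rows.append("".join(r))
        aln = AlignmentMatrix.from_sequences([(f"t{i}", r) for i, r in enumerate(rows)])
        dp = genetic_distance(aln, "p").values
        dk = genetic_distance(aln, "K2P").values
        assert np.all(dk + 1e-12 >= dp)

    def test_symmetry_and_zero_diagonal(self, rng):
        rows = [random_dna(rng, 500) for _ in range(3)]
        aln = AlignmentMatrix.from_sequences([(f"t{i}", r) for i, r in enumerate(rows)])
        d = genetic_distance(aln).values
        assert np.allclose(d, d.T, equal_nan=True)
        assert np.all(np.diag(d) == 0)
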