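"""Linker alignment, read orientation, classification and step-2 filters."""

from __future__ import annotations

import random

import pytest

import rindseq as rs
from rindseq.linkers import (
    DEFAULT_SCORING,
    TYPE_TO_CLASS,
    LinkerAlignment,
    TrimmedInsert,
    align_linker,
)

LINKERS = rs.DEFAULT_LINKERS
FIRST = LINKERS.first_linker_long


def sw_affine_score(a: str, b: str, match=1.0, mismatch=-2.0, gopen=5.0, gext=2.0):
    """Independent Smith-Waterman oracle; a gap of length L costs gopen + gext*L.

    The optimal local alignment neither starts nor ends with a gap, so
    tracking the matched-pair state suffices for the score.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - (gopen + gext), X[i - 1][j] - gext)
            Y[i][j] = max(M[i][j - 1] - (gopen + gext), Y[i][j - 1] - gext)
            if M[i][j] > best:
                best = M[i][j]
    return best


class TestAlignLinker:
    def test_linker_as_read_prefix_scores_full_length(self):
        read = FIRST + "ACGTACGTACGTACGT"
        aln = align_linker(FIRST, read)
        assert aln.score == len(FIRST)
        assert aln.n_mismatch == 0 and aln.n_gap == 0
        assert aln.read_span == (0, len(FIRST))
        assert aln.linker_span == (0, len(FIRST))
        assert aln.last10_exact

    def test_one_substitution_costs_three(self):
        # score = (len-1) matches - 2 for the mismatch = len - 3
        mid = len(FIRST) // 2
        mutated = FIRST[:mid] + ("A" if FIRST[mid] != "A" else "C") + FIRST[mid + 1 :]
        read = mutated + "GGGGCCCCAAAA"
        aln = align_linker(FIRST, read)
        assert aln.score == len(FIRST) - 3
        assert aln.n_mismatch == 1

    def test_scores_match_dp_oracle_on_random_pairs(self):
        rng = random.Random(0)
        for _ in range(25):
            read = "".join(rng.choice("ACGT") for _ in range(100))
            linker = "".join(rng.choice("ACGT") for _ in range(30))
            aln = align_linker(linker, read)
            assert aln.score == pytest.approx(sw_affine_score(read, linker))

    def test_tie_break_leftmost_read_start(self):
        probe = "ACGTTGCA"
        read = "TT" + probe + "GG" + probe + "TT"
        aln = align_linker(probe, read)
        assert aln.read_span[0] == 2  # leftmost of the two exact copies


class TestOrientRead:
    def test_minus_strand_read_flipped(self):
        read = rs.revcomp(FIRST + "ACGTAGGCTTAACC")
        oriented, orientation, aln = rs.orient_read(read)
        assert orientation == "-"
        assert oriented.startswith(FIRST)
        assert aln.read_strand_tested == "reverse-complement"

    def test_score_tie_keeps_as_is(self):
        # no linker signal at all: both orientations tie at some weak score
        read = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        _, orientation, _ = rs.orient_read(read)
        assert orientation == "+"

    def test_simulated_orientations_recovered(self, type1_library):
        _, lib = type1_library
        truth = dict(zip(lib.truth.read_id, lib.truth.orientation))
        for rid, seq in lib.reads[:200]:
            _, orientation, _ = rs.orient_read(seq)
            assert orientation == truth[rid]


class TestClassifyRead:
    def test_matches_simulator_truth_completely(self, planted_library):
        _, lib = planted_library
        classified = rs.classify_reads(lib.reads)
        truth = dict(zip(lib.truth.read_id, lib.truth["type"]))
        for t in classified:
            assert t.product_class == TYPE_TO_CLASS[truth[t.read_id]]

    def test_class_proportions_follow_screening_ratios(self, toy_genome):
        """At the realistic default mix, class proportions echo the
        no-first-linker : truncated : both-linkers screening ratios."""
        breaks = rs.plant_breaks(toy_genome, 2000, seed=21)
        lib = rs.simulate_library(
            toy_genome, breaks, params=rs.LibraryParams(n_products=10000, seed=22)
        )
        counts = {"1/3": 0, "2/4": 0, "5": 0}
        for t in rs.classify_reads(lib.reads):
            counts[t.product_class] += 1
        n = sum(counts.values())
        # 14 566 / 69 229 / 21 980 of 105 775
        assert counts["2/4"] / n == pytest.approx(14566 / 105775, abs=0.03)
        assert counts["5"] / n == pytest.approx(69229 / 105775, abs=0.03)
        assert counts["1/3"] / n == pytest.approx(21980 / 105775, abs=0.03)

    def test_strand_invariance(self, planted_library):
        _, lib = planted_library
        for rid, seq in lib.reads[:150]:
            a = rs.classify_read(seq, read_id=rid)
            b = rs.classify_read(rs.revcomp(seq), read_id=rid)
            assert a.product_class == b.product_class
            assert a.insert == b.insert

    def test_perfect_type1_insert_is_exact_fragment(self, toy_genome):
        brk = rs.plant_breaks(toy_genome, 1, seed=30)[0]
        lib = rs.simulate_library(
            toy_genome,
            [brk],
            params=rs.LibraryParams(
                n_products=1, product_mix=(1, 0, 0, 0, 0), seed=31,
                read_length_mean=500, read_length_sd=0,
            ),
        )
        t = rs.classify_read(lib.reads[0][1])
        assert t.product_class == "1/3"
        seq = toy_genome[brk.chrom]
        if brk.strand == "+":
            assert seq[brk.pos : brk.pos + len(t.insert)] == t.insert
        else:
            assert (
                rs.revcomp(seq[brk.pos - len(t.insert) + 1 : brk.pos + 1]) == t.insert
            )

    def test_primer_only_read_is_type5(self, toy_genome):
        window = toy_genome["chr1"][100:200]
        t = rs.classify_read(LINKERS.primer_first + window)
        assert t.product_class == "5"

    def test_second_linker_only_read_is_type24(self, toy_genome):
        frag = toy_genome["chr2"][50:150]
        read = LINKERS.second_linker_b + frag + LINKERS.second_read_tail
        assert rs.classify_read(read).product_class == "2/4"

    def test_every_read_gets_exactly_one_class(self, planted_library):
        _, lib = planted_library
        classified = rs.classify_reads(lib.reads)
        assert len(classified) == len(lib.reads)
        assert all(t.product_class in ("1/3", "2/4", "5") for t in classified)


def _mk_insert(insert_len: int, n_mismatch: int = 0, n_gap: int = 0) -> TrimmedInsert:
    aln = LinkerAlignment(
        linker_id="first", read_strand_tested="as-is", score=49.0,
        aligned_length=49, read_span=(0, 49), linker_span=(0, 49),
        n_mismatch=n_mismatch, n_gap=n_gap, last10_exact=True,
    )
    return TrimmedInsert("r", "1/3", "A" * insert_len, "+", aln)


class TestFilterInserts:
    def test_length_boundary(self):
        assert rs.filter_inserts([_mk_insert(10)]) == []
        kept = rs.filter_inserts([_mk_insert(11)])
        assert len(kept) == 1

    def test_mismatch_or_gap_dropped(self):
        assert rs.filter_inserts([_mk_insert(20, n_mismatch=1)]) == []
        assert rs.filter_inserts([_mk_insert(20, n_gap=1)]) == []

    def test_non_13_classes_dropped(self):
        t = _mk_insert(20)
        t.product_class = "5"
        assert rs.filter_inserts([t]) == []

    def test_error_free_retention_matches_truth(self, planted_library):
        _, lib = planted_library
        classified = rs.classify_reads(lib.reads)
        retained = {t.read_id for t in rs.filter_inserts(classified)}
        expected = {
            t.read_id
            for t in classified
            if t.product_class == "1/3" and len(t.insert) > 10
        }
        assert retained == expected
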