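"""Exact conditional inference on 2x2 tables and the 256-4-mer model."""

from __future__ import annotations

import math
import random
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

import rindseq as rs
from rindseq.association import ContingencyTable, bh_adjust, build_tables, pool_zero_kmers
from rindseq.exact import support_and_logweights

ACGT_TABLE = (124, 956, 29319, 11757514)
POOLED_TABLE = (0, 1080, 1112372, 10674461)


def brute_force_two_sided_p(A, B, C, D, rel_tie=Fraction(1, 10**7)):
    """Exhaustive integer-arithmetic oracle for the two-sided exact p.

    Sums hypergeometric point probabilities over the full conditional
    support that do not exceed the observed one (same 1e-7 relative tie
    convention as the implementation, but evaluated exactly).
    """
    n, K = A + B, A + C
    N = A + B + C + D
    lo, hi = max(0, n - (N - K)), min(n, K)
    num = {
        x: Fraction(math.comb(K, x) * math.comb(N - K, n - x))
        for x in range(lo, hi + 1)
    }
    obs = num[A] * (1 + rel_tie)
    total = sum(num.values())
    return float(sum(v for v in num.values() if v <= obs) / total)


class TestFisherExact:
    def test_identical_rows_give_p_one(self):
        assert rs.fisher_exact_two_sided(2, 8, 2, 8) == 1.0

    def test_matches_bruteforce_on_random_small_tables(self):
        rng = random.Random(42)
        cases = 0
        while cases < 200:
            A, B, C, D = (rng.randint(0, 15) for _ in range(4))
            if min(A + B, C + D, A + C, B + D) == 0:
                continue
            cases += 1
            p = rs.fisher_exact_two_sided(A, B, C, D)
            oracle = brute_force_two_sided_p(A, B, C, D)
            assert p == pytest.approx(oracle, rel=1e-9), (A, B, C, D)

    def test_matches_scipy_on_random_tables(self):
        rng = random.Random(7)
        for _ in range(100):
            A, B, C, D = (rng.randint(0, 25) for _ in range(4))
            if min(A + B, C + D, A + C, B + D) == 0:
                continue
            assert rs.fisher_exact_two_sided(A, B, C, D) == pytest.approx(
                scipy_fisher([[A, B], [C, D]]).pvalue, rel=1e-9
            )

    def test_extreme_table_finite_in_log_space(self):
        p = rs.fisher_exact_two_sided(*ACGT_TABLE)
        assert 0.0 < p < 1e-100
        assert np.isfinite(p)

    def test_upper_tail_monotone_in_a(self):
        """For fixed margins, moving mass into A never increases the
        enrichment tail probability."""
        n, K, N = 30, 40, 200

        def upper_tail_p(a):
            A, B = a, n - a
            C, D = K - a, N - K - n + a
            xs, logw = support_and_logweights(A, B, C, D)
            from scipy.special import logsumexp

            logpmf = logw - logsumexp(logw)
            return float(np.exp(logsumexp(logpmf[xs >= a])))

        tails = [upper_tail_p(a) for a in range(5, 26)]
        assert all(t2 <= t1 + 1e-12 for t1, t2 in zip(tails, tails[1:]))


class TestConditionalMle:
    def test_symmetric_table_is_one(self):
        assert rs.conditional_mle_odds_ratio(5, 5, 5, 5) == pytest.approx(1.0)

    def test_zero_a_gives_zero(self):
        assert rs.conditional_mle_odds_ratio(*POOLED_TABLE) == 0.0

    def test_maximal_a_gives_infinity(self):
        assert rs.conditional_mle_odds_ratio(5, 0, 5, 10) == math.inf

    def test_reference_convention_matches_published_environment(self):
        """Reference mode reproduces the classical fisher.test output for
        the large enrichment table (2 dp: 51.96)."""
        assert rs.conditional_mle_odds_ratio(*ACGT_TABLE) == pytest.approx(
            51.9629, abs=5e-4
        )

    def test_precise_convention_solves_score_equation(self):
        """Precise mode returns the psi with E[A-cell | psi] = A (the
        cross-check is scipy's independent conditional-MLE implementation)."""
        est = rs.conditional_mle_odds_ratio(*ACGT_TABLE, convention="precise")
        ref = scipy_odds_ratio(
            [[124, 956], [29319, 11757514]], kind="conditional"
        ).statistic
        assert est == pytest.approx(ref, rel=1e-6)

    def test_matches_scipy_on_random_tables(self):
        rng = random.Random(3)
        checked = 0
        while checked < 60:
            A, B, C, D = (rng.randint(0, 12) for _ in range(4))
            if min(A + B, A + C) == 0:
                continue
            est = rs.conditional_mle_odds_ratio(A, B, C, D, convention="precise")
            ref = scipy_odds_ratio([[A, B], [C, D]], kind="conditional").statistic
            if 0 < est < math.inf:
                assert est == pytest.approx(ref, rel=1e-5), (A, B, C, D)
                checked += 1

    def test_strictly_increasing_in_a_on_interior(self):
        margins_n, margins_k = 20, 15
        values = []
        for a in range(1, 15):
            table = (a, margins_n - a, margins_k - a, 100 - margins_k - margins_n + a)
            values.append(
                rs.conditional_mle_odds_ratio(*table, convention="precise")
            )
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_degenerate_margins_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            rs.conditional_mle_odds_ratio(0, 0, 5, 5)


class TestExactCi:
    def test_reference_bounds_for_large_table(self):
        lo, hi = rs.exact_ci(*ACGT_TABLE)
        assert lo == pytest.approx(42.7610, abs=5e-4)
        assert hi == pytest.approx(62.8910, abs=5e-4)

    def test_pooled_zero_table_bounds(self):
        lo, hi = rs.exact_ci(*POOLED_TABLE)
        assert lo == 0.0
        assert round(hi, 2) == 0.03

    def test_ci_contains_estimate_and_widens(self):
        rng = random.Random(11)
        for _ in range(25):
            A, B, C, D = (rng.randint(1, 12) for _ in range(4))
            est = rs.conditional_mle_odds_ratio(A, B, C, D, convention="precise")
            lo95, hi95 = rs.exact_ci(A, B, C, D, 0.95, convention="precise")
            lo99, hi99 = rs.exact_ci(A, B, C, D, 0.99, convention="precise")
            assert lo95 <= est <= hi95
            assert lo99 <= lo95 and hi99 >= hi95

    def test_matches_scipy_exact_interval(self):
        rng = random.Random(19)
        for _ in range(30):
            A, B, C, D = (rng.randint(0, 10) for _ in range(4))
            if min(A + B, A + C) == 0:
                continue
            lo, hi = rs.exact_ci(A, B, C, D, convention="precise")
            ref = scipy_odds_ratio(
                [[A, B], [C, D]], kind="conditional"
            ).confidence_interval(0.95)
            assert lo == pytest.approx(ref.low, rel=1e-4, abs=1e-8)
            if math.isinf(hi):
                assert math.isinf(ref.high)
            else:
                assert hi == pytest.approx(ref.high, rel=1e-4)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_hand_computed_example(self):
        # step-up: (0.01*3/1, 0.02*3/2, 0.03*3/3) -> min suffix = 0.03 each
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_rank_one_times_m(self):
        p = [1e-20] + [0.5] * 255
        adj = bh_adjust(p)
        assert adj[0] == pytest.approx(1e-20 * 256)

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(5)
        p = rng.random(100)
        adj = bh_adjust(p)
        assert (adj <= 1).all() and (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestBuildTables:
    def test_margins_constant_across_tables(self, toy_genome):
        gk = rs.count_genome_kmers(toy_genome, 4)
        counts = {"ACGT": 10, "AAAA": 5, "TTTT": 1}
        tables = build_tables(counts, gk)
        assert len(tables) == 256
        assert {t.reads_total for t in tables.values()} == {16}
        assert {t.genome_total for t in tables.values()} == {gk.total}
        assert tables["ACGT"].A == 10 and tables["GGGG"].A == 0

    def test_empty_reads_rejected(self, toy_genome):
        gk = rs.count_genome_kmers(toy_genome, 4)
        with pytest.raises(ValueError, match="empty read margin"):
            build_tables({}, gk)

    def test_pool_conserves_genome_margin(self, toy_genome):
        gk = rs.count_genome_kmers(toy_genome, 4)
        tables = build_tables({"ACGT": 3, "AAAA": 2}, gk)
        pooled = pool_zero_kmers(tables)
        observed_c = sum(t.C for t in tables.values() if t.A > 0)
        assert pooled.C + observed_c == gk.total
        assert pooled.A == 0 and pooled.B == 5

    def test_pool_empty_when_all_observed(self, toy_genome):
        gk = rs.count_genome_kmers(toy_genome, 4)
        counts = {k: 1 for k in tables_keys()}
        tables = build_tables(counts, gk)
        assert pool_zero_kmers(tables) is None


def tables_keys():
    from rindseq.genome import all_kmers

    return all_kmers(4)


class TestModelFit:
    def test_planted_motif_ranks_first(self, planted_library, toy_genome):
        _, lib = planted_library
        result = rs.run_pipeline(lib.reads, toy_genome, compute_ci=False)
        res = result.association
        assert res.top_kmer() == "ACGT"
        assert res.frame.iloc[0]["significant"]
        assert res.frame.iloc[0]["rank"] == 1

    def test_frame_invariants(self, planted_library, toy_genome):
        _, lib = planted_library
        res = rs.run_pipeline(lib.reads, toy_genome, compute_ci=False).association
        f = res.frame
        assert len(f) == 256
        assert (f["A"] + f["B"]).nunique() == 1
        assert (f["C"] + f["D"]).nunique() == 1
        assert (f["p_adj"] >= f["p_raw"] - 1e-15).all()
        assert (f["p_adj"].diff().dropna() >= -1e-12).all()  # sorted by rank
        # OR = 0 exactly when A = 0
        assert ((f["odds_ratio"] == 0) == (f["A"] == 0)).all()

    def test_summary_and_histogram(self, planted_library, toy_genome):
        _, lib = planted_library
        res = rs.run_pipeline(lib.reads, toy_genome).association
        text = res.summary()
        assert "ACGT" in text and "pooled" in text
        hist = res.or_range_histogram()
        assert sum(hist.values()) == 256
        assert hist["OR = 0"] == int((res.frame["A"] == 0).sum())

    def test_to_tsv_roundtrip(self, planted_library, toy_genome, tmp_path):
        import pandas as pd

        _, lib = planted_library
        res = rs.run_pipeline(lib.reads, toy_genome).association
        res.to_tsv(tmp_path / "table.tsv")
        df = pd.read_csv(tmp_path / "table.tsv", sep="\t")
        assert len(df) == 256 + (1 if res.pooled is not None else 0)
        assert df.iloc[0]["kmer"] == "ACGT"
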