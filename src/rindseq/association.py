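"""Breakpoint k-mer association model: 256 exact tests against the genome.

For every 4-mer ``m`` a 2x2 contingency table compares stitched reads
with the genome:

====================  ==================  =======================
..                    4-mer is m          4-mer is anything else
====================  ==================  =======================
stitched reads        A                   B
genome positions      C                   D
====================  ==================  =======================

A + B is the number of countable stitched reads (constant across all
256 tables) and C + D the number of plus-strand 4-mer windows in the
genome.  Each table receives a two-sided Fisher exact p (computed in
log space), a Benjamini-Hochberg adjusted p across the 256 tests, a
conditional-MLE odds ratio and a central exact conditional 95% CI.
4-mers never observed before a break are additionally pooled into a
single depletion table.

The module follows the model/results idiom: build a
:class:`KmerAssociation` from the counts (or directly from stitched
reads and a genome), call :meth:`~KmerAssociation.fit`, and read
estimates off the returned :class:`KmerAssociationResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .catalog import PatternSpec, StitchedRead, count_patterns
from .exact import conditional_mle_odds_ratio, exact_ci, fisher_exact_two_sided
from .genome import Genome, KmerCountTable, all_kmers, count_genome_kmers

__all__ = [
    "ContingencyTable",
    "KmerTestResult",
    "KmerAssociation",
    "KmerAssociationResults",
    "build_tables",
    "bh_adjust",
    "pool_zero_kmers",
]


@dataclass(frozen=True)
class ContingencyTable:
    """One 4-mer's 2x2 table of read counts vs genome counts."""

    A: int  # stitched reads with the focal 4-mer before the break
    B: int  # stitched reads with any other 4-mer
    C: int  # genome positions with the focal 4-mer
    D: int  # genome positions with any other 4-mer

    def __post_init__(self) -> None:
        for name in "ABCD":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.A, self.B, self.C, self.D)

    @property
    def reads_total(self) -> int:
        return self.A + self.B

    @property
    def genome_total(self) -> int:
        return self.C + self.D

    @property
    def sample_odds_ratio(self) -> float:
        """Cross-product (A*D)/(B*C); not the estimate this package reports."""
        if self.B == 0 or self.C == 0:
            return float("inf") if self.A * self.D > 0 else float("nan")
        return (self.A * self.D) / (self.B * self.C)


@dataclass(frozen=True)
class KmerTestResult:
    kmer: str
    table: ContingencyTable
    p_raw: float
    p_adj: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    rank: int


def build_tables(
    pattern_counts: Mapping[str, int], genome_kmers: KmerCountTable
) -> dict[str, ContingencyTable]:
    """One contingency table per 4-mer from read-side and genome-side counts."""
    if genome_kmers.k != 4:
        raise ValueError("genome k-mer table must have k=4")
    kmers = all_kmers(4)
    unknown = set(pattern_counts) - set(kmers)
    if unknown:
        raise ValueError(f"pattern counts contain non-4-mer keys: {sorted(unknown)}")
    reads_total = sum(pattern_counts.values())
    if reads_total == 0:
        raise ValueError("no countable stitched reads: empty read margin")
    genome_total = genome_kmers.total
    tables = {}
    for m in kmers:
        a = int(pattern_counts.get(m, 0))
        c = int(genome_kmers.counts[m])
        tables[m] = ContingencyTable(
            A=a, B=reads_total - a, C=c, D=genome_total - c
        )
    return tables


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def pool_zero_kmers(
    tables: Mapping[str, ContingencyTable]
) -> Optional[ContingencyTable]:
    """Pool every 4-mer with A = 0 into one depletion table, if any exist."""
    zero = [t for t in tables.values() if t.A == 0]
    if not zero:
        return None
    any_table = next(iter(tables.values()))
    pooled_c = sum(t.C for t in zero)
    return ContingencyTable(
        A=0,
        B=any_table.reads_total,
        C=pooled_c,
        D=any_table.genome_total - pooled_c,
    )


class KmerAssociation:
    """Model: breakpoint 4-mer counts vs genome-wide 4-mer background.

    Parameters
    ----------
    pattern_counts
        Reads per preceding 4-mer (the 4 bases immediately 5' of the
        break), zero-filled or sparse over the 256 keys.
    genome_kmers
        Plus-strand overlapping 4-mer counts of the reference genome.

    Examples
    --------
    >>> model = KmerAssociation.from_stitched(stitched_reads, genome)
    >>> res = model.fit()
    >>> res.frame.head()
    """

    def __init__(
        self,
        pattern_counts: Mapping[str, int],
        genome_kmers: KmerCountTable,
    ):
        self.tables = build_tables(pattern_counts, genome_kmers)
        self.pattern_counts = dict(pattern_counts)
        self.genome_kmers = genome_kmers

    @classmethod
    def from_stitched(
        cls, stitched: Iterable[StitchedRead], genome: Genome
    ) -> "KmerAssociation":
        counts = count_patterns(stitched, PatternSpec(4, 0))
        return cls(counts, count_genome_kmers(genome, k=4))

    def fit(
        self,
        alpha: float = 0.05,
        compute_ci: bool = True,
        convention: str = "reference",
    ) -> "KmerAssociationResults":
        """Run all 256 exact tests plus the pooled zero-count table.

        ``compute_ci=False`` skips the per-4-mer odds-ratio CI bounds
        (the slowest part) when only ranking and significance matter.
        """
        kmers = sorted(self.tables)
        p_raw = np.array(
            [fisher_exact_two_sided(*self.tables[m].cells) for m in kmers]
        )
        p_adj = bh_adjust(p_raw)
        results = []
        for m, pr, pa in zip(kmers, p_raw, p_adj):
            t = self.tables[m]
            orr = conditional_mle_odds_ratio(*t.cells, convention=convention)
            if compute_ci:
                lo, hi = exact_ci(*t.cells, convention=convention)
            else:
                lo = hi = float("nan")
            results.append(
                KmerTestResult(
                    kmer=m, table=t, p_raw=float(pr), p_adj=float(pa),
                    odds_ratio=orr, ci_low=lo, ci_high=hi, rank=-1,
                )
            )
        # rank by adjusted then raw p, ties by kmer for stability
        order = sorted(
            range(len(results)),
            key=lambda i: (results[i].p_adj, results[i].p_raw, results[i].kmer),
        )
        ranked = [None] * len(results)
        for rank, i in enumerate(order, start=1):
            r = results[i]
            ranked[i] = KmerTestResult(
                kmer=r.kmer, table=r.table, p_raw=r.p_raw, p_adj=r.p_adj,
                odds_ratio=r.odds_ratio, ci_low=r.ci_low, ci_high=r.ci_high,
                rank=rank,
            )

        pooled_table = pool_zero_kmers(self.tables)
        pooled = None
        if pooled_table is not None:
            pr = fisher_exact_two_sided(*pooled_table.cells)
            lo, hi = exact_ci(*pooled_table.cells, convention=convention)
            pooled = KmerTestResult(
                kmer="pooled_zero",
                table=pooled_table,
                p_raw=pr,
                p_adj=pr,  # single post-hoc test: no multiplicity adjustment
                odds_ratio=conditional_mle_odds_ratio(
                    *pooled_table.cells, convention=convention
                ),
                ci_low=lo,
                ci_high=hi,
                rank=0,
            )
        return KmerAssociationResults(
            model=self, results=ranked, pooled=pooled, alpha=alpha
        )


class KmerAssociationResults:
    """Fitted per-4-mer exact tests with BH-FDR control.

    Attributes
    ----------
    frame : pandas.DataFrame
        One row per 4-mer, sorted by adjusted p (columns: kmer, A, B, C,
        D, p_raw, p_adj, odds_ratio, ci_low, ci_high, significant).
    pooled : KmerTestResult or None
        The pooled table of 4-mers never observed before a break
        (``None`` when every 4-mer was observed at least once).
    """

    def __init__(
        self,
        model: KmerAssociation,
        results: Sequence[KmerTestResult],
        pooled: Optional[KmerTestResult],
        alpha: float,
    ):
        self.model = model
        self.results = list(results)
        self.pooled = pooled
        self.alpha = alpha
        rows = [
            {
                "kmer": r.kmer,
                "A": r.table.A, "B": r.table.B, "C": r.table.C, "D": r.table.D,
                "p_raw": r.p_raw, "p_adj": r.p_adj,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "significant": r.p_adj < alpha,
                "rank": r.rank,
            }
            for r in self.results
        ]
        self.frame = (
            pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)
        )

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]]

    def top_kmer(self) -> str:
        """The 4-mer with the smallest adjusted p."""
        return str(self.frame.iloc[0]["kmer"])

    def or_range_histogram(self) -> dict[str, int]:
        """Counts of 4-mers in the odds-ratio bins 0, (0,1], (1,10], >10."""
        ors = self.frame["odds_ratio"].to_numpy()
        return {
            "OR = 0": int((ors == 0).sum()),
            "0 < OR <= 1": int(((ors > 0) & (ors <= 1)).sum()),
            "1 < OR <= 10": int(((ors > 1) & (ors <= 10)).sum()),
            "OR > 10": int((ors > 10).sum()),
        }

    def summary(self, top: int = 10) -> str:
        """Human-readable report of the top-ranked and pooled tests."""
        lines = [
            "Breakpoint 4-mer association (exact conditional inference)",
            f"  stitched reads: {self.results[0].table.reads_total}"
            f"   genome 4-mer windows: {self.results[0].table.genome_total}",
            f"  significant 4-mers (BH-adjusted p < {self.alpha:g}): "
            f"{int(self.frame['significant'].sum())}",
            "",
            f"{'kmer':>6} {'A':>5} {'C':>9} {'p_adj':>10} "
            f"{'OR':>8} {'95% CI':>16}",
        ]
        for _, row in self.frame.head(top).iterrows():
            ci = (
                f"({row.ci_low:6.2f},{row.ci_high:7.2f})"
                if np.isfinite(row.ci_low)
                else "      (n/a)"
            )
            lines.append(
                f"{row.kmer:>6} {row.A:>5d} {row.C:>9d} {row.p_adj:>10.3g} "
                f"{row.odds_ratio:>8.2f} {ci:>16}"
            )
        if self.pooled is not None:
            t = self.pooled.table
            lines += [
                "",
                "pooled 4-mers never observed before a break:",
                f"  A=0 B={t.B} C={t.C} D={t.D}  p={self.pooled.p_raw:.3g}  "
                f"OR={self.pooled.odds_ratio:.2f} "
                f"CI=({self.pooled.ci_low:.2f}, {self.pooled.ci_high:.2f})",
            ]
        hist = self.or_range_histogram()
        lines += ["", "odds-ratio ranges: "
                  + "  ".join(f"{k}: {v}" for k, v in hist.items())]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        frame = self.frame.copy()
        if self.pooled is not None:
            t = self.pooled.table
            pooled_row = pd.DataFrame(
                [
                    {
                        "kmer": "pooled_zero", "A": t.A, "B": t.B,
                        "C": t.C, "D": t.D,
                        "p_raw": self.pooled.p_raw, "p_adj": self.pooled.p_adj,
                        "odds_ratio": self.pooled.odds_ratio,
                        "ci_low": self.pooled.ci_low,
                        "ci_high": self.pooled.ci_high,
                        "significant": self.pooled.p_raw < self.alpha,
                        "rank": 0,
                    }
                ]
            )
            frame = pd.concat([frame, pooled_row], ignore_index=True)
        frame.to_csv(path, sep="\t", index=False)
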