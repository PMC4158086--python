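"""Stitched reads, the per-position break catalog, and breakpoint k-mer counts.

A *stitched read* is a 100-column construct: columns 1-50 hold the 50
reference bases immediately 5' of the break on the mapped strand, and
columns 51-100 hold the first 50 read bases, so the break always sits
between columns 50 and 51.  Columns missing because the read is short or
the break lies near a chromosome edge are masked with ``.``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genome import Genome, revcomp
from .mapping import MappedBreak

MASK = "."
N_CONTEXT = 50  # reference columns 5' of the break
N_READ = 50  # read columns 3' of the break

#: Supported (bases before break, bases after break) pattern windows.
SUPPORTED_PATTERNS = {(3, 1), (4, 0), (2, 2), (4, 1), (4, 2), (6, 0), (6, 2)}


@dataclass(frozen=True)
class PatternSpec:
    """A breakpoint-centred k-mer window: n bases before + n after the break."""

    n_before: int
    n_after: int

    def __post_init__(self) -> None:
        if (self.n_before, self.n_after) not in SUPPORTED_PATTERNS:
            raise ValueError(
                f"unsupported pattern window {self.n_before}+{self.n_after}; "
                f"supported: {sorted(SUPPORTED_PATTERNS)}"
            )

    @property
    def k(self) -> int:
        return self.n_before + self.n_after


@dataclass(frozen=True)
class StitchedRead:
    """100 columns around one break; ``columns[49]``/``columns[50]`` flank it."""

    read_id: str
    chrom: str
    pos: int
    strand: str
    columns: str  # length 100, "." where masked

    def __post_init__(self) -> None:
        if len(self.columns) != N_CONTEXT + N_READ:
            raise ValueError("stitched read must have exactly 100 columns")


def stitch(brk: MappedBreak, read_prefix: str, genome: Genome) -> StitchedRead:
    """Build the stitched read for one retained break call.

    The 50-base context is taken 5' of the break on the mapped strand:
    for a plus-strand break at ``pos`` it is ``genome[pos-50:pos]``, for
    a minus-strand break the reverse complement of the plus-strand bases
    at ``[pos+1, pos+51)``.  Missing columns are masked.
    """
    seq = genome[brk.chrom]
    pos = brk.break_pos
    if not (0 <= pos < len(seq)):
        raise ValueError(
            f"break position {pos} outside chromosome {brk.chrom} (len {len(seq)})"
        )
    if brk.strand == "+":
        lo = max(0, pos - N_CONTEXT)
        context = seq[lo:pos]
    else:
        hi = min(len(seq), pos + 1 + N_CONTEXT)
        context = revcomp(seq[pos + 1 : hi])
    context = MASK * (N_CONTEXT - len(context)) + context
    read_part = read_prefix[:N_READ]
    read_part = read_part + MASK * (N_READ - len(read_part))
    return StitchedRead(
        read_id=brk.read_id,
        chrom=brk.chrom,
        pos=pos,
        strand=brk.strand,
        columns=context + read_part,
    )


class BreakCatalog:
    """Read counts aggregated per (chrom, break position, strand)."""

    def __init__(self, counts: Mapping[tuple[str, int, str], int]):
        self.counts: dict[tuple[str, int, str], int] = dict(counts)

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_positions(self) -> int:
        return len(self.counts)

    def per_chromosome(self) -> dict[str, int]:
        """Read counts per chromosome."""
        out: Counter[str] = Counter()
        for (chrom, _, _), c in self.counts.items():
            out[chrom] += c
        return dict(out)

    def plus_strand_proportion(self) -> dict[str, float]:
        """Per-chromosome proportion of reads mapped to the plus strand."""
        plus: Counter[str] = Counter()
        total: Counter[str] = Counter()
        for (chrom, _, strand), c in self.counts.items():
            total[chrom] += c
            if strand == "+":
                plus[chrom] += c
        return {chrom: plus[chrom] / total[chrom] for chrom in total}


def build_catalog(breaks: Iterable[MappedBreak]) -> BreakCatalog:
    """Aggregate uniquely mapped break calls into a positional catalog."""
    counts: Counter[tuple[str, int, str]] = Counter()
    for b in breaks:
        if not b.unique:
            raise ValueError(
                f"read {b.read_id}: only uniquely mapped breaks enter the catalog"
            )
        counts[(b.chrom, b.break_pos, b.strand)] += 1
    return BreakCatalog(counts)


def chrom_size_correlation(
    catalog: BreakCatalog, genome: Genome
) -> tuple[float, float]:
    """Pearson correlation of per-chromosome break counts vs lengths.

    Chromosomes with no catalogued breaks contribute a zero count.
    Returns (r, two-sided p from the t transform).
    """
    if len(genome) < 3:
        raise ValueError("need at least 3 chromosomes")
    per_chrom = catalog.per_chromosome()
    lengths = np.array([genome.lengths[c] for c in genome.names], dtype=float)
    counts = np.array([per_chrom.get(c, 0) for c in genome.names], dtype=float)
    if np.ptp(lengths) == 0 or np.ptp(counts) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = stats.pearsonr(lengths, counts)
    return float(r), float(p)


def count_patterns(
    stitched: Iterable[StitchedRead], spec: PatternSpec
) -> dict[str, int]:
    """Count breakpoint-window k-mers over stitched reads.

    A read contributes iff every required column is unmasked; keys cover
    all ``4**k`` possible windows (zero-filled).
    """
    counts = {"".join(p): 0 for p in product("ACGT", repeat=spec.k)}
    lo = N_CONTEXT - spec.n_before
    hi = N_CONTEXT + spec.n_after
    for sr in stitched:
        window = sr.columns[lo:hi]
        if MASK in window:
            continue
        counts[window] += 1
    return counts


def pattern_proportions(counts: Mapping[str, int]) -> dict[str, float]:
    """Counts normalized by the number of contributing reads."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: v / total for k, v in counts.items()}


def write_stitched_tsv(stitched: Sequence[StitchedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcolumns\tstrand\tchrom\tpos\n")
        for sr in stitched:
            fh.write(f"{sr.read_id}\t{sr.columns}\t{sr.strand}\t{sr.chrom}\t{sr.pos}\n")


def write_pattern_tsv(counts: Mapping[str, int], path: str | Path) -> None:
    """Pattern counts + proportions as TSV, sorted by descending count."""
    props = pattern_proportions(counts)
    with open(path, "w") as fh:
        fh.write("pattern\tcount\tproportion\n")
        for k in sorted(counts, key=lambda x: (-counts[x], x)):
            fh.write(f"{k}\t{counts[k]}\t{props[k]:.6g}\n")


def plot_catalog(
    catalog: BreakCatalog, genome: Genome, path: str | Path
) -> None:
    """Per-chromosome break-position plot (one horizontal track per chromosome)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = genome.names
    fig, ax = plt.subplots(figsize=(10, 0.4 * len(names) + 1))
    for y, name in enumerate(names):
        ax.hlines(y, 0, genome.lengths[name], color="0.8", lw=2)
        xs = [pos for (chrom, pos, _), _ in catalog.counts.items() if chrom == name]
        hs = [c for (chrom, _, _), c in catalog.counts.items() if chrom == name]
        for x, h in zip(xs, hs):
            ax.vlines(x, y, y + min(0.08 * h, 0.45), color="tab:blue", lw=0.8)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("chromosome")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
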