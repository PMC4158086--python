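"""Synthetic LM-PCR double-strand-break sequencing libraries with ground truth.

Ligation-mediated PCR (LM-PCR) amplifies the unknown sequence next to a
DNA break by ligating a known "First linker" to the broken end, digesting
with a blunt 4-cutter (RsaI), ligating a "Second linker" to the cut end,
and amplifying between linker primers.  A sequencing library derived
from such a protocol contains five product types:

1. First linker + break-adjacent genomic fragment + Second linker;
2. Second linkers flanking an ordinary enzyme fragment (no break);
3. both linkers flanking a chimera of several ligated enzyme fragments,
   whose first fragment starts at a break;
4. Second linkers flanking a chimera (no break);
5. nonspecific amplicons carrying the First-linker *primer* only, i.e.
   missing the 10 terminal linker bases next to the break.

This module generates genomes with a configurable base composition,
plants breaks with a configurable 4-mer preference, and emits reads of
all five types together with a per-read ground-truth table, so that
every downstream screening and statistics stage can be tested without
any external sequencing data.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import RSAI, Enzyme, Genome, all_kmers, cut_positions, revcomp

# Base composition of the S. cerevisiae genome (A, C, G, T).
YEAST_COMPOSITION = (0.309, 0.192, 0.191, 0.308)

# sacCer3 chromosome lengths (bp), used to shape toy genomes.
YEAST_CHROM_LENGTHS = (
    230218, 813184, 316620, 1531933, 576874, 270161, 1090940, 562643,
    439888, 745751, 666816, 1078177, 924431, 784333, 1091291, 948066,
)


def yeast_like_lengths(total_bp: int, n_chrom: int = 16) -> list[int]:
    """Chromosome lengths proportional to the real yeast karyotype."""
    props = np.asarray(YEAST_CHROM_LENGTHS[:n_chrom], dtype=float)
    props /= props.sum()
    lengths = np.maximum(np.round(props * total_bp).astype(int), 200)
    return [int(x) for x in lengths]


@dataclass(frozen=True)
class LinkerSet:
    """The adapter/primer sequences of the LM-PCR design."""

    first_linker_long: str = (
        "AGGTAACGAGTCAGACCACCGATCGCTCGGAAGCTTACCTCGTGGACGT"
    )
    first_linker_short: str = "ACGTCCACGAG"
    second_linker_a: str = "ATGGTACCACCCGTAGGCCCTACCGGTACC"
    second_linker_b: str = "GGTACCGGTAGGGCCTACGGGTGGTACCAT"
    primer_first: str = "AGGTAACGAGTCAGACCACCGA"
    primer_second: str = "GGTACCGGTAGGGCCTACGGGT"

    def __post_init__(self) -> None:
        if not self.first_linker_long.startswith(self.primer_first):
            raise ValueError("primer_first must be a prefix of first_linker_long")
        if not self.second_linker_b.startswith(self.primer_second):
            raise ValueError("primer_second must be a prefix of second_linker_b")

    @property
    def first_last10(self) -> str:
        """The 10 terminal First-linker bases adjacent to the break."""
        return self.first_linker_long[-10:]

    @property
    def second_read_tail(self) -> str:
        """Second-linker sequence as it appears at a read's 3' end.

        The read is sequenced from the First-linker primer, so the
        Second linker enters the read as the reverse complement of its
        primer-bearing strand.  (As printed, the two Second-linker
        oligonucleotides are not exact reverse complements of each
        other; the primer-bearing strand ``second_linker_b`` defines
        read construction.)
        """
        return revcomp(self.second_linker_b)


DEFAULT_LINKERS = LinkerSet()


@dataclass(frozen=True)
class TruthBreak:
    """A planted break: first genomic base 3' of the break on ``strand``.

    ``preceding4`` is the 4-mer immediately 5' of the break on the break
    strand; for a minus-strand break at plus-coordinate ``pos`` it is the
    reverse complement of the plus-strand bases at ``[pos+1, pos+5)``.
    """

    chrom: str
    pos: int
    strand: str
    preceding4: str


# Default product mix, shaped after the gross screening proportions of a
# real library (types 1+3 : 2+4 : 5 roughly 21 : 14 : 65) -- a
# convenience default for realistic class ratios, not a ground truth.
DEFAULT_PRODUCT_MIX = (0.16, 0.07, 0.048, 0.068, 0.654)


@dataclass(frozen=True)
class LibraryParams:
    """Knobs of the library simulator (all randomness flows from ``seed``)."""

    n_products: int = 10000
    product_mix: tuple[float, float, float, float, float] = DEFAULT_PRODUCT_MIX
    read_length_mean: float = 150.0
    read_length_sd: float = 30.0
    min_read_length: int = 40
    chimera_fragment_count_range: tuple[int, int] = (2, 4)
    substitution_error_rate: float = 0.0
    seed: int = 0
    enzyme: Enzyme = RSAI
    break_sampling: str = "replacement"  # or "unique": each break sequenced <= once

    def __post_init__(self) -> None:
        if self.n_products < 0:
            raise ValueError("n_products must be non-negative")
        mix = np.asarray(self.product_mix, dtype=float)
        if len(mix) != 5 or (mix < 0).any() or (mix > 1).any():
            raise ValueError("product_mix must be 5 probabilities in [0, 1]")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("product_mix must sum to 1 within 1e-9")
        if not (0.0 <= self.substitution_error_rate < 1.0):
            raise ValueError("substitution_error_rate must be in [0, 1)")
        lo, hi = self.chimera_fragment_count_range
        if lo < 2 or hi < lo:
            raise ValueError("chimera_fragment_count_range must be (lo>=2, hi>=lo)")
        if self.break_sampling not in ("replacement", "unique"):
            raise ValueError("break_sampling must be 'replacement' or 'unique'")


def generate_genome(
    n_chrom: int,
    lengths: Sequence[int],
    composition: Sequence[float] = YEAST_COMPOSITION,
    seed: int = 0,
) -> Genome:
    """Random genome with i.i.d. bases drawn from ``composition`` (A,C,G,T)."""
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have n_chrom entries")
    comp = np.asarray(composition, dtype=float)
    if len(comp) != 4 or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be 4 non-negative proportions summing to 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    chroms = {}
    for i, length in enumerate(lengths, start=1):
        if length <= 0:
            raise ValueError("chromosome lengths must be positive")
        chroms[f"chr{i}"] = "".join(rng.choice(bases, size=length, p=comp))
    return Genome(chroms)


def _preceding4_weights(
    genome: Genome, weight_of: np.ndarray
) -> tuple[list[tuple[str, str, int]], np.ndarray]:
    """Per-(chrom, strand, pos) sampling weight for break planting.

    A break at (chrom, pos, +) has preceding 4-mer genome[pos-4:pos];
    at (chrom, pos, -) it is revcomp(genome[pos+1:pos+5]).  Eligible
    positions leave at least one genomic base 3' of the break.
    """
    from .genome import _kmer_codes  # reuse the fast coder

    rc_code = np.zeros(256, dtype=np.int64)
    kmers = all_kmers(4)
    index = {k: i for i, k in enumerate(kmers)}
    for i, k in enumerate(kmers):
        rc_code[i] = index[revcomp(k)]

    entries: list[tuple[str, str, int]] = []
    weights: list[np.ndarray] = []
    for name, seq in genome.chromosomes.items():
        codes = _kmer_codes(seq, 4)  # code of 4-mer starting at each position
        # plus strand: break before pos in [4, L-1]; preceding 4-mer starts at pos-4
        plus_codes = codes[: len(seq) - 4]  # positions pos = 4 .. L-1
        w_plus = np.where(plus_codes >= 0, weight_of[np.maximum(plus_codes, 0)], 0.0)
        entries.append((name, "+", 4))
        weights.append(w_plus)
        # minus strand: pos in [0, L-5]; preceding4 = revcomp of plus 4-mer at pos+1
        minus_codes = codes[1:]  # 4-mer starting at pos+1, pos = 0 .. L-5
        w_minus = np.where(
            minus_codes >= 0, weight_of[rc_code[np.maximum(minus_codes, 0)]], 0.0
        )
        entries.append((name, "-", 0))
        weights.append(w_minus)
    return entries, weights


def plant_breaks(
    genome: Genome,
    n_breaks: int,
    motif_weights: dict[str, float] | None = None,
    seed: int = 0,
    default_weight: float = 1.0,
) -> list[TruthBreak]:
    """Draw break positions with a configurable preceding-4-mer preference.

    The probability that a break lands immediately 3' of 4-mer ``m`` is
    proportional to ``weight(m)`` times the genome occurrence count of
    ``m`` (strands are weighted symmetrically; each eligible position
    carries the weight of its own preceding 4-mer).  ``motif_weights``
    overrides ``default_weight`` per 4-mer, so ``{"ACGT": 50}`` with the
    default weight 1 enriches breaks after ACGT 50-fold per occurrence.
    Positions are drawn with replacement: several breaks may share a
    coordinate, as in a cell population.
    """
    weight_of = np.full(256, float(default_weight))
    if motif_weights:
        index = {k: i for i, k in enumerate(all_kmers(4))}
        for kmer, w in motif_weights.items():
            kmer = kmer.upper()
            if kmer not in index:
                raise ValueError(f"not a 4-mer over ACGT: {kmer!r}")
            if w < 0:
                raise ValueError("motif weights must be non-negative")
            weight_of[index[kmer]] = float(w)
    if (weight_of < 0).any() or not (weight_of > 0).any():
        raise ValueError("weights must be non-negative with at least one positive")

    entries, weight_arrays = _preceding4_weights(genome, weight_of)
    total_weight = sum(float(w.sum()) for w in weight_arrays)
    if total_weight <= 0:
        raise ValueError("no eligible break positions under these weights")

    rng = np.random.default_rng(seed)
    # two-stage draw (positions with replacement): segment by total
    # weight, then positions within each segment in one vectorized call
    seg_probs = np.array([float(w.sum()) for w in weight_arrays]) / total_weight
    seg_counts = rng.multinomial(n_breaks, seg_probs)
    breaks: list[TruthBreak] = []
    for seg, count in enumerate(seg_counts):
        if count == 0:
            continue
        name, strand, offset = entries[seg]
        w = weight_arrays[seg]
        idxs = rng.choice(len(w), size=count, p=w / w.sum())
        seq = genome[name]
        for idx in idxs:
            pos = int(idx) + offset
            if strand == "+":
                prec = seq[pos - 4 : pos]
            else:
                prec = revcomp(seq[pos + 1 : pos + 5])
            breaks.append(
                TruthBreak(chrom=name, pos=pos, strand=strand, preceding4=prec)
            )
    return breaks


def motif_weight_for_fraction(
    genome: Genome, motif: str, fraction: float, default_weight: float = 1.0
) -> float:
    """Weight for ``motif`` so the expected break fraction after it is ``fraction``.

    Uses the genome's own preceding-4-mer opportunity counts (both
    strands), inverting ``f = w*c_m / (w*c_m + sum_other c)``.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    weight_one = np.ones(256)
    entries, weight_arrays = _preceding4_weights(genome, weight_one)
    # count opportunities per 4-mer: weight 1 everywhere means array of 0/1
    index = {k: i for i, k in enumerate(all_kmers(4))}
    target = np.zeros(256)
    target[index[motif.upper()]] = 1.0
    _, motif_arrays = _preceding4_weights(genome, target)
    c_m = sum(float(w.sum()) for w in motif_arrays)
    c_tot = sum(float(w.sum()) for w in weight_arrays)
    c_other = c_tot - c_m
    if c_m <= 0:
        raise ValueError(f"motif {motif!r} never precedes an eligible position")
    return default_weight * (fraction / (1.0 - fraction)) * (c_other / c_m)


def breaks_at_enzyme_sites(
    genome: Genome, enzyme: Enzyme, n_breaks: int, seed: int = 0
) -> list[TruthBreak]:
    """Breaks at restriction-cut positions (control-library construction).

    Emulates a control in which the First linker is ligated to the blunt
    ends produced by the enzyme itself, so every "break" coincides with
    a cut site on a random strand.
    """
    sites: list[tuple[str, int, str]] = []
    for name, seq in genome.chromosomes.items():
        for c in cut_positions(seq, enzyme):
            if 4 <= c <= len(seq) - 1:
                sites.append((name, c, "+"))
            if 0 <= c - 1 <= len(seq) - 5:
                sites.append((name, c - 1, "-"))
    if not sites:
        raise ValueError("genome contains no enzyme sites")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(sites), size=n_breaks)
    out = []
    for i in picks:
        name, pos, strand = sites[i]
        seq = genome[name]
        prec = seq[pos - 4 : pos] if strand == "+" else revcomp(seq[pos + 1 : pos + 5])
        out.append(TruthBreak(chrom=name, pos=pos, strand=strand, preceding4=prec))
    return out


@dataclass
class SimulatedLibrary:
    """Reads plus per-read ground truth from one simulator run."""

    reads: list[tuple[str, str]]  # (read_id, sequence)
    truth: pd.DataFrame  # read_id, type, chrom, pos, strand, preceding4, orientation

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f">{rid}\n{seq}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


class _FragmentIndex:
    """Per-chromosome enzyme cut positions and plus-strand fragments."""

    def __init__(self, genome: Genome, enzyme: Enzyme):
        self.cuts: dict[str, list[int]] = {}
        self.fragments: list[tuple[str, int, int]] = []
        for name, seq in genome.chromosomes.items():
            cuts = [c for c in cut_positions(seq, enzyme) if 0 < c < len(seq)]
            self.cuts[name] = cuts
            bounds = [0] + cuts + [len(seq)]
            for a, b in zip(bounds, bounds[1:]):
                self.fragments.append((name, a, b))

    def next_cut(self, chrom: str, pos: int, length: int) -> int:
        """First cut position strictly greater than pos, else chromosome end."""
        cuts = self.cuts[chrom]
        i = bisect.bisect_right(cuts, pos)
        return cuts[i] if i < len(cuts) else length

    def prev_cut(self, chrom: str, pos: int) -> int:
        """Last cut position <= pos, else chromosome start."""
        cuts = self.cuts[chrom]
        i = bisect.bisect_right(cuts, pos)
        return cuts[i - 1] if i > 0 else 0


def _break_fragment(genome: Genome, frag_index: _FragmentIndex, brk: TruthBreak) -> str:
    """Genomic sequence from a break to the nearest downstream enzyme cut.

    On the plus strand the fragment runs rightward from ``pos`` to the
    next cut (or the chromosome end); on the minus strand leftward from
    ``pos`` to the previous cut, reported 5'->3' on the minus strand.
    """
    seq = genome[brk.chrom]
    if brk.strand == "+":
        end = frag_index.next_cut(brk.chrom, brk.pos, len(seq))
        return seq[brk.pos : end]
    start = frag_index.prev_cut(brk.chrom, brk.pos)
    return revcomp(seq[start : brk.pos + 1])


def simulate_library(
    genome: Genome,
    breaks: Sequence[TruthBreak],
    linkers: LinkerSet = DEFAULT_LINKERS,
    params: LibraryParams = LibraryParams(),
) -> SimulatedLibrary:
    """Emit an LM-PCR read library of all five product types with truth rows.

    Reads are emitted on a random strand (the whole amplicon may be
    reverse complemented), truncated to a sequencing read length drawn
    from Normal(mean, sd) floored at ``min_read_length``, and subjected
    to i.i.d. substitution errors.  For products carrying the First
    linker, the truncation point is clamped past the full linker: such
    reads are sequenced from the First-linker primer, and a read too
    short to cover its own linker would not be a type-1/3 product.
    """
    mix = np.asarray(params.product_mix, dtype=float)
    if mix[0] + mix[2] > 0 and not breaks:
        raise ValueError("product mix assigns mass to types 1/3 but no breaks given")

    rng = np.random.default_rng(params.seed)
    break_queue: list[int] = []
    if params.break_sampling == "unique" and breaks:
        break_queue = list(rng.permutation(len(breaks)))

    def draw_break() -> TruthBreak:
        # "replacement": several reads may sequence the same break event,
        # as PCR resampling of a small break pool would.  "unique": each
        # break event yields at most one read — the regime of a large
        # cell population where break molecules far outnumber reads.
        if params.break_sampling == "replacement":
            return breaks[rng.integers(0, len(breaks))]
        if not break_queue:
            raise ValueError(
                "break_sampling='unique' exhausted the break list; "
                "plant at least as many breaks as type-1/3 products"
            )
        return breaks[break_queue.pop()]

    frag_index = _FragmentIndex(genome, params.enzyme)
    fragments = frag_index.fragments
    second_tail = linkers.second_read_tail
    bases = "ACGT"
    chrom_names = genome.names

    reads: list[tuple[str, str]] = []
    rows: list[dict] = []

    def random_fragment_seq() -> str:
        name, a, b = fragments[rng.integers(0, len(fragments))]
        frag = genome[name][a:b]
        return frag if rng.random() < 0.5 else revcomp(frag)

    def random_window(mean_len: int = 100) -> str:
        name = chrom_names[rng.integers(0, len(chrom_names))]
        seq = genome[name]
        length = min(len(seq), max(20, int(rng.normal(mean_len, 30))))
        start = rng.integers(0, len(seq) - length + 1)
        window = seq[start : start + length]
        return window if rng.random() < 0.5 else revcomp(window)

    types = rng.choice(5, size=params.n_products, p=mix) + 1
    for i, ptype in enumerate(types):
        rid = f"read{i:06d}"
        brk: TruthBreak | None = None
        if ptype == 1:
            brk = draw_break()
            amplicon = (
                linkers.first_linker_long
                + _break_fragment(genome, frag_index, brk)
                + second_tail
            )
        elif ptype == 2:
            amplicon = (
                linkers.second_linker_b + random_fragment_seq() + second_tail
            )
        elif ptype == 3:
            brk = draw_break()
            nfrag = int(
                rng.integers(
                    params.chimera_fragment_count_range[0],
                    params.chimera_fragment_count_range[1] + 1,
                )
            )
            chimera = _break_fragment(genome, frag_index, brk) + "".join(
                random_fragment_seq() for _ in range(nfrag - 1)
            )
            amplicon = linkers.first_linker_long + chimera + second_tail
        elif ptype == 4:
            nfrag = int(
                rng.integers(
                    params.chimera_fragment_count_range[0],
                    params.chimera_fragment_count_range[1] + 1,
                )
            )
            chimera = "".join(random_fragment_seq() for _ in range(nfrag))
            amplicon = linkers.second_linker_b + chimera + second_tail
        else:  # nonspecific primer-derived amplicon
            amplicon = linkers.primer_first + random_window()

        read_len = max(
            params.min_read_length,
            int(round(rng.normal(params.read_length_mean, params.read_length_sd))),
        )
        if ptype in (1, 3):
            read_len = max(read_len, len(linkers.first_linker_long) + 1)
        read = amplicon[:read_len]

        if params.substitution_error_rate > 0:
            arr = list(read)
            hits = np.nonzero(
                rng.random(len(arr)) < params.substitution_error_rate
            )[0]
            for j in hits:
                choices = bases.replace(arr[j], "") if arr[j] in bases else bases
                arr[j] = choices[rng.integers(0, len(choices))]
            read = "".join(arr)

        orientation = "+" if rng.random() < 0.5 else "-"
        if orientation == "-":
            read = revcomp(read)

        reads.append((rid, read))
        rows.append(
            {
                "read_id": rid,
                "type": int(ptype),
                "chrom": brk.chrom if brk else "",
                "pos": brk.pos if brk else -1,
                "strand": brk.strand if brk else "",
                "preceding4": brk.preceding4 if brk else "",
                "orientation": orientation,
            }
        )

    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id", "type", "chrom", "pos", "strand", "preceding4", "orientation",
        ],
    )
    return SimulatedLibrary(reads=reads, truth=truth)
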