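"""Mapping retained inserts to the genome (screening steps 3-5).

The insert's first base is the base immediately 3' of the break, so an
alignment anchored at the first query base pins the break coordinate.
The built-in mapper reports maximal exact-prefix matches of the insert
on both strands (seeded on the first 11 bases, keeping only the hits
that achieve the longest extension); hits from an external BLAST
tabular file can be ingested instead and pass through the same filters.

Multi-mapped reads are retained only when more than 90% of their mapped
positions share the same preceding 4-mer — strictly more, so a 9-of-10
split is rejected — because only that 4-mer context, not the coordinate,
feeds the breakpoint statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genome import Genome, revcomp
from .linkers import TrimmedInsert

SEED_LENGTH = 11  # minimum anchored match; inserts <= 10 never reach mapping


@dataclass(frozen=True)
class MapHit:
    """One alignment of an insert: leftmost reference coordinate + strand."""

    chrom: str
    start: int  # 0-based leftmost reference coordinate of the hit
    strand: str  # "+" | "-"
    query_start: int  # 0-based first aligned query base
    aligned_length: int
    identity: float = 1.0

    @property
    def break_pos(self) -> int:
        """Reference coordinate where the read's first base maps.

        On the minus strand the read runs right-to-left on the plus
        coordinates, so its first base sits at the hit's right edge.
        """
        if self.strand == "+":
            return self.start
        return self.start + self.aligned_length - 1


@dataclass(frozen=True)
class MappedBreak:
    """A retained read's break call: coordinate, strand, context 4-mer."""

    read_id: str
    chrom: str
    break_pos: int
    strand: str
    unique: bool
    prior4: Optional[str]  # None when < 4 reference bases precede the break
    n_hits: int = 1


def prior4_at(genome: Genome, chrom: str, pos: int, strand: str) -> Optional[str]:
    """The 4-mer immediately 5' of a break on the mapped strand, if present."""
    seq = genome[chrom]
    if strand == "+":
        if pos < 4:
            return None
        return seq[pos - 4 : pos]
    if pos + 5 > len(seq):
        return None
    return revcomp(seq[pos + 1 : pos + 5])


def positions_near_start(brk: MappedBreak, genome: Genome) -> bool:
    """True iff at least 4 reference bases exist 5' of the break."""
    return prior4_at(genome, brk.chrom, brk.break_pos, brk.strand) is not None


def _prefix_hits_on_sequence(insert: str, seq: str) -> list[tuple[int, int]]:
    """(start, extension length) of maximal matches of the insert prefix."""
    seed = insert[:SEED_LENGTH]
    hits = []
    start = seq.find(seed)
    n, L = len(insert), len(seq)
    while start != -1:
        length = SEED_LENGTH
        while length < n and start + length < L and seq[start + length] == insert[length]:
            length += 1
        hits.append((start, length))
        start = seq.find(seed, start + 1)
    return hits


def map_insert(insert: str, genome: Genome) -> list[MapHit]:
    """All maximal exact-prefix matches of the insert on both strands.

    Matches are seeded on the first ``SEED_LENGTH`` bases and extended
    maximally; only hits achieving the longest extension observed for
    this insert are reported (the built-in analogue of best-hit
    filtering).  Inserts shorter than the seed return no hits.
    """
    if len(insert) < SEED_LENGTH:
        return []
    raw: list[MapHit] = []
    for name, seq in genome.chromosomes.items():
        for start, length in _prefix_hits_on_sequence(insert, seq):
            raw.append(MapHit(name, start, "+", 0, length))
        rc = genome.revcomp_of(name)
        L = len(seq)
        for start, length in _prefix_hits_on_sequence(insert, rc):
            raw.append(MapHit(name, L - start - length, "-", 0, length))
    if not raw:
        return []
    best = max(h.aligned_length for h in raw)
    return [h for h in raw if h.aligned_length == best]


def filter_first_base(hits: Iterable[MapHit]) -> list[MapHit]:
    """Retain hits aligned from the first query base only."""
    return [h for h in hits if h.query_start == 0]


_STRAND_ORDER = {"+": 0, "-": 1}


def resolve_multimap(
    read_id: str, hits: Sequence[MapHit], genome: Genome
) -> tuple[Optional[MappedBreak], str]:
    """Resolve a read's first-base hits into a break call, or reject.

    A single hit is a unique break.  With several hits the read is
    retained iff the modal preceding 4-mer covers strictly more than 90%
    of the mapped positions; the representative coordinate is the lowest
    (chrom, pos, strand) among the modal-context hits.  Returns
    ``(MappedBreak | None, reason)`` with reason one of ``"unique"``,
    ``"multi_retained"``, ``"multi_rejected"``, ``"unmapped"``.
    """
    if not hits:
        return None, "unmapped"
    if any(h.query_start != 0 for h in hits):
        raise ValueError("resolve_multimap expects first-base-anchored hits")
    if len(hits) == 1:
        h = hits[0]
        return (
            MappedBreak(
                read_id=read_id,
                chrom=h.chrom,
                break_pos=h.break_pos,
                strand=h.strand,
                unique=True,
                prior4=prior4_at(genome, h.chrom, h.break_pos, h.strand),
                n_hits=1,
            ),
            "unique",
        )
    contexts = [
        prior4_at(genome, h.chrom, h.break_pos, h.strand) for h in hits
    ]
    counted = Counter(c for c in contexts if c is not None)
    if not counted:
        return None, "multi_rejected"
    modal, modal_count = counted.most_common(1)[0]
    if modal_count <= 0.9 * len(hits):  # "> 90%" is strict
        return None, "multi_rejected"
    modal_hits = [h for h, c in zip(hits, contexts) if c == modal]
    rep = min(
        modal_hits, key=lambda h: (h.chrom, h.break_pos, _STRAND_ORDER[h.strand])
    )
    return (
        MappedBreak(
            read_id=read_id,
            chrom=rep.chrom,
            break_pos=rep.break_pos,
            strand=rep.strand,
            unique=False,
            prior4=modal,
            n_hits=len(hits),
        ),
        "multi_retained",
    )


def map_inserts(
    inserts: Iterable[TrimmedInsert], genome: Genome
) -> tuple[list[MappedBreak], list[str], dict[str, int]]:
    """Map retained inserts and resolve multimapping.

    Returns (retained break calls, first-50-bases read prefixes aligned
    with the break calls, audit counters).  The read prefix accompanies
    each break so stitched reads can be built downstream.
    """
    breaks: list[MappedBreak] = []
    prefixes: list[str] = []
    audit = Counter(unique=0, multi_retained=0, multi_rejected=0, unmapped=0)
    for ins in inserts:
        hits = filter_first_base(map_insert(ins.insert, genome))
        brk, reason = resolve_multimap(ins.read_id, hits, genome)
        audit[reason] += 1
        if brk is not None:
            breaks.append(brk)
            prefixes.append(ins.insert[:50])
    audit["input"] = audit["unique"] + audit["multi_retained"] + (
        audit["multi_rejected"] + audit["unmapped"]
    )
    return breaks, prefixes, dict(audit)


# -- external BLAST import ---------------------------------------------------

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(path: str | Path) -> dict[str, list[MapHit]]:
    """Parse BLAST outfmt-6 hits into first-base-testable MapHits per read.

    BLAST coordinates are 1-based inclusive; a minus-strand hit has
    ``sstart > send``.  ``query_start`` is taken on the oriented query
    (``qstart - 1``), so the first-base filter applies unchanged.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)
    out: dict[str, list[MapHit]] = {}
    for row in df.itertuples(index=False):
        if row.sstart <= row.send:
            strand, start = "+", int(row.sstart) - 1
            aligned = int(row.send) - int(row.sstart) + 1
        else:
            strand, start = "-", int(row.send) - 1
            aligned = int(row.sstart) - int(row.send) + 1
        hit = MapHit(
            chrom=str(row.sseqid),
            start=start,
            strand=strand,
            query_start=int(row.qstart) - 1,
            aligned_length=aligned,
            identity=float(row.pident) / 100.0,
        )
        out.setdefault(str(row.qseqid), []).append(hit)
    return out


def breaks_to_bed(breaks: Iterable[MappedBreak], path: str | Path) -> None:
    """Write break calls as BED-like TSV (0-based half-open interval)."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tread_id\tn_hits\tstrand\tprior4\tunique\n"
        )
        for b in breaks:
            fh.write(
                f"{b.chrom}\t{b.break_pos}\t{b.break_pos + 1}\t{b.read_id}\t"
                f"{b.n_hits}\t{b.strand}\t{b.prior4 or '.'}\t{int(b.unique)}\n"
            )
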