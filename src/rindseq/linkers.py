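"""Linker trimming and PCR-product classification (screening steps 1-2).

Reads are oriented by aligning the First linker against the read and its
reverse complement, then classified into three screening categories:

``"1/3"``
    First linker accepted — all three criteria hold: (1) aligned length
    greater than 10 and no longer than the linker, (2) the alignment
    sits at the read's 5' end (it starts within one linker length of the
    read start), (3) the last ten linker bases match exactly with no
    gaps.  These are the break-carrying products (intact or chimeric;
    the two are separated downstream by mappability, not here).

``"5"``
    First-linker evidence passing (1) and (2) but failing the exact
    last-10 match — nonspecific amplicons primed by the First-linker
    primer, missing the linker tail next to the break.

``"2/4"``
    No usable First-linker evidence (Second-linker-only products).

Alignment is local (Smith-Waterman) with affine gaps under the scoring
+1 match / -2 mismatch / -5 gap open / -2 gap extension, where a gap of
length L costs ``5 + 2L``.  Second-linker removal is best-effort with no
acceptance criteria; residue left in the insert is tolerated because
mapping is anchored at the insert's first base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio import Align

from .genome import revcomp
from .simulate import DEFAULT_LINKERS, LinkerSet

PRODUCT_CLASSES = ("1/3", "2/4", "5")

#: Screening class implied by each true product type.
TYPE_TO_CLASS = {1: "1/3", 2: "2/4", 3: "1/3", 4: "2/4", 5: "5"}


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine local-alignment scoring; a gap of length L costs open + extend*L."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        # PairwiseAligner charges the opening score on the first gap
        # base, so open+extend reproduces the "open + extend*L" total.
        aligner.open_gap_score = self.gap_open + self.gap_extend
        aligner.extend_gap_score = self.gap_extend
        return aligner


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class LinkerAlignment:
    """Best local alignment of one linker against one read orientation."""

    linker_id: str  # "first" | "second"
    read_strand_tested: str  # "as-is" | "reverse-complement"
    score: float
    aligned_length: int  # alignment columns (incl. gap columns)
    read_span: tuple[int, int]  # 0-based half-open on the tested read
    linker_span: tuple[int, int]  # 0-based half-open on the linker
    n_mismatch: int
    n_gap: int
    last10_exact: bool


@dataclass
class TrimmedInsert:
    """A classified read: screening class plus the retained genomic insert."""

    read_id: str
    product_class: str  # "1/3" | "2/4" | "5"
    insert: str
    orientation: str  # "+" read used as-is, "-" reverse complemented
    first_alignment: Optional[LinkerAlignment] = None


def _extract_alignment(
    aln, linker: str, read: str, linker_id: str, tested: str
) -> LinkerAlignment:
    """Pull span/mismatch/gap statistics out of a Biopython alignment."""
    read_blocks, linker_blocks = aln.aligned  # target=read, query=linker
    read_span = (int(read_blocks[0][0]), int(read_blocks[-1][1]))
    linker_span = (int(linker_blocks[0][0]), int(linker_blocks[-1][1]))
    n_mismatch = 0
    aligned_pairs = 0
    for (rs, re), (ls, le) in zip(read_blocks, linker_blocks):
        aligned_pairs += re - rs
        n_mismatch += sum(
            1 for a, b in zip(read[rs:re], linker[ls:le]) if a != b
        )
    gap_read = (read_span[1] - read_span[0]) - aligned_pairs
    gap_linker = (linker_span[1] - linker_span[0]) - aligned_pairs
    n_gap = gap_read + gap_linker
    aligned_length = aligned_pairs + n_gap

    last10 = False
    L = len(linker)
    if linker_span[1] == L:
        for (rs, re), (ls, le) in zip(read_blocks, linker_blocks):
            if le == L and ls <= L - 10:
                tail_read = read[re - 10 : re]
                last10 = tail_read == linker[L - 10 :]
                break
    return LinkerAlignment(
        linker_id=linker_id,
        read_strand_tested=tested,
        score=float(aln.score),
        aligned_length=aligned_length,
        read_span=read_span,
        linker_span=linker_span,
        n_mismatch=n_mismatch,
        n_gap=n_gap,
        last10_exact=last10,
    )


_MAX_TIE_ALTERNATIVES = 64


def align_linker(
    linker: str,
    read: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    linker_id: str = "first",
    read_strand_tested: str = "as-is",
) -> LinkerAlignment:
    """Best-scoring local alignment of ``linker`` against ``read``.

    Ties between equal-scoring optima are broken deterministically:
    leftmost read start, then leftmost linker start.
    """
    if not linker or not read:
        raise ValueError("linker and read must be non-empty")
    aligner = scoring.make_aligner()
    alignments = aligner.align(read, linker)
    best = None
    best_key = None
    for i, aln in enumerate(alignments):
        if i >= _MAX_TIE_ALTERNATIVES:
            break
        cand = _extract_alignment(aln, linker, read, linker_id, read_strand_tested)
        key = (cand.read_span[0], cand.linker_span[0])
        if best is None or key < best_key:
            best, best_key = cand, key
    assert best is not None
    return best


def _exact_prefix_alignment(
    linker: str, start: int, linker_id: str, tested: str
) -> LinkerAlignment:
    """Synthesized alignment record for an exact full-linker occurrence."""
    return LinkerAlignment(
        linker_id=linker_id,
        read_strand_tested=tested,
        score=float(len(linker)),
        aligned_length=len(linker),
        read_span=(start, start + len(linker)),
        linker_span=(0, len(linker)),
        n_mismatch=0,
        n_gap=0,
        last10_exact=True,
    )


def orient_read(
    read: str,
    linkers: LinkerSet = DEFAULT_LINKERS,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> tuple[str, str, LinkerAlignment]:
    """Choose the read orientation with the higher First-linker score.

    Returns (oriented read, orientation "+"/"-", winning first-linker
    alignment).  Score ties resolve to the as-is orientation.
    """
    fwd = align_linker(linkers.first_linker_long, read, scoring, "first", "as-is")
    rc = revcomp(read)
    rev = align_linker(
        linkers.first_linker_long, rc, scoring, "first", "reverse-complement"
    )
    if rev.score > fwd.score:
        return rc, "-", rev
    return read, "+", fwd


def _trim_second_linker(seq: str, linkers: LinkerSet, min_overlap: int = 6) -> str:
    """Best-effort removal of Second-linker residue at the 3' end."""
    tail = linkers.second_read_tail
    idx = seq.find(tail)
    if idx != -1:
        return seq[:idx]
    # amplicon may be truncated inside the Second linker: suffix of the
    # read matching a prefix of the linker tail
    max_ov = min(len(tail) - 1, len(seq))
    for k in range(max_ov, min_overlap - 1, -1):
        if seq.endswith(tail[:k]):
            return seq[: len(seq) - k]
    return seq


def classify_read(
    read: str,
    linkers: LinkerSet = DEFAULT_LINKERS,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    read_id: str = "",
) -> TrimmedInsert:
    """Assign a screening class and extract the genomic insert.

    Exact-structure reads (no sequencing errors in the linker region)
    are recognized by direct string comparison; everything else falls
    back to local alignment under the configured scoring.  Every read
    receives exactly one class.
    """
    first = linkers.first_linker_long
    # fast paths: exact linker structures, common in low-error libraries
    for oriented, orientation in ((read, "+"), (revcomp(read), "-")):
        if oriented.startswith(first):
            aln = _exact_prefix_alignment(first, 0, "first", "as-is")
            insert = _trim_second_linker(oriented[len(first) :], linkers)
            return TrimmedInsert(read_id, "1/3", insert, orientation, aln)
    for oriented, orientation in ((read, "+"), (revcomp(read), "-")):
        if oriented.startswith(linkers.primer_first) and not oriented.startswith(
            first
        ):
            # primer present, full linker absent: check the tail is truly
            # missing before calling it nonspecific
            if linkers.first_last10 not in oriented[: len(first) + 4]:
                aln = align_linker(first, oriented, scoring, "first", "as-is")
                insert = _trim_second_linker(
                    oriented[aln.read_span[1] :], linkers
                )
                return TrimmedInsert(read_id, "5", insert, orientation, aln)
    if read.startswith(linkers.second_linker_b) or revcomp(read).startswith(
        linkers.second_linker_b
    ):
        orientation = "+" if read.startswith(linkers.second_linker_b) else "-"
        return TrimmedInsert(read_id, "2/4", "", orientation, None)

    # slow path: alignment-based decision
    oriented, orientation, aln = orient_read(read, linkers, scoring)
    c1 = 10 < aln.aligned_length <= len(first)
    c2 = aln.read_span[0] < len(first)
    c3 = aln.last10_exact
    if c1 and c2 and c3:
        insert = _trim_second_linker(oriented[aln.read_span[1] :], linkers)
        return TrimmedInsert(read_id, "1/3", insert, orientation, aln)
    if c1 and c2:
        insert = _trim_second_linker(oriented[aln.read_span[1] :], linkers)
        return TrimmedInsert(read_id, "5", insert, orientation, aln)
    return TrimmedInsert(read_id, "2/4", "", orientation, aln)


def classify_reads(
    reads: Iterable[tuple[str, str]],
    linkers: LinkerSet = DEFAULT_LINKERS,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> list[TrimmedInsert]:
    """Classify a whole library of (read_id, sequence) pairs."""
    return [classify_read(seq, linkers, scoring, read_id=rid) for rid, seq in reads]


def filter_inserts(inserts: Iterable[TrimmedInsert]) -> list[TrimmedInsert]:
    """Screening step 2: keep class-1/3 inserts longer than 10 bases whose
    First-linker alignment has zero mismatches and zero gaps."""
    kept = []
    for ins in inserts:
        if ins.product_class != "1/3":
            continue
        if len(ins.insert) <= 10:
            continue
        aln = ins.first_alignment
        if aln is None or aln.n_mismatch > 0 or aln.n_gap > 0:
            continue
        kept.append(ins)
    return kept
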