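"""Reference-genome handling.

FASTA I/O, strand arithmetic, in-silico restriction digestion and
genome-wide k-mer counting.  Coordinates are 0-based, half-open
everywhere; sequences are stored uppercase over the alphabet
``{A, C, G, T, N}``.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """An ordered collection of named chromosome sequences.

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to uppercase A/C/G/T(/N) sequence.
        Insertion order is preserved and meaningful.
    """

    chromosomes: dict[str, str]
    _revcomp_cache: dict[str, str] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for name, seq in self.chromosomes.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
                )
            clean[name] = seq
        self.chromosomes = clean

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def revcomp_of(self, name: str) -> str:
        """Reverse complement of a chromosome, cached (used by the mapper)."""
        rc = self._revcomp_cache.get(name)
        if rc is None:
            rc = revcomp(self.chromosomes[name])
            self._revcomp_cache[name] = rc
        return rc


def read_fasta(path: str | Path | io.TextIOBase) -> Genome:
    """Read a (possibly wrapped) multi-record FASTA file into a Genome.

    Raises
    ------
    ValueError
        On malformed input, naming the offending line where possible.
    """
    if isinstance(path, io.TextIOBase):
        text = path.read()
        source = "<stream>"
    else:
        text = Path(path).read_text()
        source = str(path)
    lines = text.splitlines()
    first_content = next(
        (i for i, line in enumerate(lines, start=1) if line.strip()), None
    )
    if first_content is None:
        raise ValueError(f"{source}: empty FASTA file")
    if not lines[first_content - 1].lstrip().startswith(">"):
        raise ValueError(
            f"{source}, line {first_content}: expected a '>' header line"
        )
    # Pre-scan for alphabet problems so errors carry a line number;
    # the actual record assembly is left to Biopython.
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(">"):
            continue
        bad = set(stripped.upper()) - VALID_BASES
        if bad:
            raise ValueError(
                f"{source}, line {lineno}: invalid sequence characters {sorted(bad)}"
            )
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    chroms: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{source}: record {rec.id!r} has an empty sequence")
        if rec.id in chroms:
            raise ValueError(f"{source}: duplicate record name {rec.id!r}")
        chroms[rec.id] = seq
    return Genome(chroms)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    """Write a Genome as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class Enzyme:
    """A blunt/staggered restriction enzyme as a recognition site plus cut offset.

    ``cut_offset`` counts bases 5' of the cut within the site on the top
    strand, so RsaI (GT^AC) is ``Enzyme("RsaI", "GTAC", 2)``.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValueError("cut_offset must lie within the recognition site")
        if set(self.recognition) - set("ACGT"):
            raise ValueError("recognition site must be over A/C/G/T")


RSAI = Enzyme("RsaI", "GTAC", 2)
ALUI = Enzyme("AluI", "AGCT", 2)


def cut_positions(sequence: str, enzyme: Enzyme) -> list[int]:
    """0-based positions at which the enzyme cuts ``sequence``.

    A cut at position ``c`` separates ``sequence[:c]`` from ``sequence[c:]``.
    Recognition sites containing N never match.
    """
    site = enzyme.recognition
    cuts = []
    start = sequence.find(site)
    while start != -1:
        cuts.append(start + enzyme.cut_offset)
        start = sequence.find(site, start + 1)
    return cuts


def digest(sequence: str, enzyme: Enzyme) -> list[int]:
    """Fragment lengths from a complete in-silico digestion.

    Terminal fragments are included; lengths always sum to
    ``len(sequence)``.  An empty sequence yields an empty list.
    """
    if not sequence:
        return []
    cuts = cut_positions(sequence, enzyme)
    bounds = [0] + [c for c in cuts if 0 < c < len(sequence)] + [len(sequence)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def fragment_histogram(
    genome: Genome,
    enzyme: Enzyme,
    assumed_break_motif: str | None = None,
) -> dict[int, int]:
    """Histogram of digestion fragment lengths over all chromosomes.

    If ``assumed_break_motif`` is given, an additional cut is placed
    immediately 3' of every plus-strand occurrence of the motif,
    emulating breaks co-existing with the enzyme's cuts.
    """
    hist: Counter[int] = Counter()
    for seq in genome.chromosomes.values():
        cuts = set(cut_positions(seq, enzyme))
        if assumed_break_motif:
            motif = assumed_break_motif.upper()
            start = seq.find(motif)
            while start != -1:
                cuts.add(start + len(motif))
                start = seq.find(motif, start + 1)
        bounds = [0] + sorted(c for c in cuts if 0 < c < len(seq)) + [len(seq)]
        hist.update(b - a for a, b in zip(bounds, bounds[1:]))
    return dict(hist)


@dataclass
class KmerCountTable:
    """Genome-wide k-mer counts on the plus strand with overlapping windows.

    ``counts`` covers all ``4**k`` keys (zero-filled); windows containing
    N are excluded from the counts but not from the key set.
    """

    k: int
    counts: dict[str, int]
    total: int

    def __getitem__(self, kmer: str) -> int:
        return self.counts[kmer]


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

def all_kmers(k: int) -> list[str]:
    """All 4**k k-mers in lexicographic order."""
    return ["".join(p) for p in product("ACGT", repeat=k)]


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of each k-window; windows containing N coded -1."""
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = arr[j : j + n]
        codes = codes * 4 + np.where(window >= 0, window, 0)
        valid &= window >= 0
    codes[~valid] = -1
    return codes


def count_genome_kmers(genome: Genome, k: int = 4) -> KmerCountTable:
    """Count overlapping k-mers on the plus strand of every chromosome."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 12:
        raise ValueError("k > 12 would enumerate an impractically large key set")
    min_len = min(genome.lengths.values())
    if k > min_len:
        raise ValueError(
            f"k={k} exceeds the shortest chromosome length ({min_len})"
        )
    agg = np.zeros(4**k, dtype=np.int64)
    for seq in genome.chromosomes.values():
        codes = _kmer_codes(seq, k)
        codes = codes[codes >= 0]
        agg += np.bincount(codes, minlength=4**k)
    keys = all_kmers(k)
    counts = {kmer: int(c) for kmer, c in zip(keys, agg)}
    return KmerCountTable(k=k, counts=counts, total=int(agg.sum()))


def base_composition(genome: Genome) -> dict[str, float]:
    """Proportions of A, C, G, T over all chromosomes (N ignored)."""
    counts = Counter()
    for seq in genome.chromosomes.values():
        counts.update(seq)
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        raise ValueError("genome contains no A/C/G/T bases")
    return {b: counts[b] / total for b in "ACGT"}


def write_count_table(
    counts: Mapping[str, int] | Mapping[int, int], path: str | Path
) -> None:
    """Write a key/count mapping as two-column TSV sorted by key."""
    with open(path, "w") as fh:
        fh.write("key\tcount\n")
        for key in sorted(counts):
            fh.write(f"{key}\t{counts[key]}\n")
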