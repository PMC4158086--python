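"""End-to-end orchestration: reads -> screening -> mapping -> statistics.

``run_pipeline`` chains the screening steps exactly as the individual
modules define them — classify and trim linkers, retain clean class-1/3
inserts longer than 10 bases, map with first-base anchoring, resolve
multimapping by shared preceding 4-mers — then builds stitched reads,
the unique-break catalog and the k-mer association fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .association import KmerAssociation, KmerAssociationResults
from .catalog import (
    BreakCatalog,
    PatternSpec,
    StitchedRead,
    build_catalog,
    count_patterns,
    stitch,
)
from .genome import Genome, count_genome_kmers
from .linkers import (
    DEFAULT_LINKERS,
    DEFAULT_SCORING,
    AlignmentScoring,
    LinkerSet,
    TrimmedInsert,
    classify_reads,
    filter_inserts,
)
from .mapping import MappedBreak, map_inserts


@dataclass
class PipelineResult:
    """Everything the screening + statistics run produced."""

    classified: list[TrimmedInsert]
    retained: list[TrimmedInsert]
    breaks: list[MappedBreak]  # retained break calls (unique + multi)
    stitched: list[StitchedRead]
    catalog: BreakCatalog  # uniquely mapped reads only
    pattern_counts: dict[str, int]
    association: Optional[KmerAssociationResults]
    audit: dict[str, int] = field(default_factory=dict)

    @property
    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {"1/3": 0, "2/4": 0, "5": 0}
        for t in self.classified:
            out[t.product_class] += 1
        return out


def run_pipeline(
    reads: Iterable[tuple[str, str]],
    genome: Genome,
    linkers: LinkerSet = DEFAULT_LINKERS,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    pattern_spec: PatternSpec = PatternSpec(4, 0),
    fit: bool = True,
    alpha: float = 0.05,
    compute_ci: bool = True,
) -> PipelineResult:
    """Run the full screening and association analysis on a read library.

    Stitched reads and pattern counts include retained multi-mapped
    reads (their shared context 4-mer is what the statistics use); the
    positional catalog holds uniquely mapped reads only.
    """
    classified = classify_reads(reads, linkers, scoring)
    retained = filter_inserts(classified)
    breaks, prefixes, audit = map_inserts(retained, genome)
    audit["classified"] = len(classified)
    audit["retained_step2"] = len(retained)

    stitched = [stitch(b, p, genome) for b, p in zip(breaks, prefixes)]
    catalog = build_catalog([b for b in breaks if b.unique])
    pattern_counts = count_patterns(stitched, pattern_spec)

    association = None
    if fit and pattern_spec == PatternSpec(4, 0) and sum(pattern_counts.values()):
        model = KmerAssociation(pattern_counts, count_genome_kmers(genome, k=4))
        association = model.fit(alpha=alpha, compute_ci=compute_ci)
    return PipelineResult(
        classified=classified,
        retained=retained,
        breaks=breaks,
        stitched=stitched,
        catalog=catalog,
        pattern_counts=pattern_counts,
        association=association,
        audit=audit,
    )
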