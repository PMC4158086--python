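# Methods

## The assay model

`rindseq` analyses ligation-mediated-PCR (LM-PCR) libraries built on
DNA double-strand break ends. A First linker is ligated to the broken
(blunted) end; the DNA is digested with RsaI (GT^AC, blunt); a Second
linker is ligated to the cut end; the fragment between linker primers
is amplified and sequenced from the First-linker side. Five product
structures can reach the sequencer:

1. First linker + break-to-cut genomic fragment + Second linker — the
   informative product: the first insert base is the base immediately
   3′ of a break;
2. Second linkers flanking an ordinary RsaI–RsaI fragment;
3. both linkers flanking a chimera of re-ligated small fragments whose
   first fragment starts at a break;
4. Second linkers flanking a chimera;
5. nonspecific amplicons primed directly by the First-linker *primer*,
   which therefore lack the 10 terminal linker bases next to the break.

The screening pipeline separates these by linker structure (types 2/4
lack First-linker evidence; type 5 lacks the last-10 exact match), by a
step-2 purity filter (insert > 10 bases, 0 mismatches, 0 gaps in the
First linker), and by mappability (type-3 chimeras of sub-seed
fragments fail first-base-anchored mapping; chimeras whose first
fragment is long enough map to a genuine break and are retained, which
is exactly the right behaviour).

## Linker alignment

Local (Smith–Waterman) alignment with affine gaps: match +1, mismatch
−2, and a gap of length L costing 5 + 2L, via Biopython's
`PairwiseAligner` (`open_gap_score = −7`, `extend_gap_score = −2`,
because that implementation charges the opening score on the first gap
base). Local mode is the only mode under which "aligned length no
longer than the linker" is meaningful while tolerating partial linkers.
Ties between equal-scoring optima break to the leftmost read start,
then leftmost linker start; orientation ties keep the read as-is.
The linker-acceptance rule "the alignment sits at the read's 5′ end" is
operationalized as *alignment starts within one linker length of the
read start*, which rejects internally aligned linkers.

Reads whose linker region is error-free are recognized by direct string
comparison before any alignment is attempted; this fast path is exactly
equivalent for such reads (score = linker length, 0 mismatches/gaps)
and keeps pipeline-scale runs fast. Second-linker removal is
best-effort (full-occurrence search, then suffix–prefix overlap ≥ 6);
leftover residue is harmless because mapping anchors at the insert's
first base.

## Mapping

The built-in mapper reports maximal exact-prefix matches of each insert
on both strands, seeded on the insert's first 11 bases; only hits
achieving the longest extension for that insert are kept (a best-hit
rule that prevents spurious 11-bp multi-hits on small genomes). Hits
from an external BLAST run (tabular outfmt 6) can be ingested instead
and flow through the same filters; coordinates are converted to 0-based
half-open, and for minus-strand hits the read's first base sits at the
hit's right edge. A multi-mapped read is retained iff strictly more
than 90 % of its positions share the same preceding 4-mer (9/10 is
rejected); the retained record carries the modal 4-mer and, as a
deterministic representative, the lowest (chrom, pos, strand) among
modal hits — only the 4-mer feeds the statistics. Multi-mapped retained
reads contribute to stitched reads and k-mer counts, but the
per-position catalog and the chromosome-size correlation use uniquely
mapped reads only.

## Stitched reads and counting

A stitched read has 100 columns: 50 reference bases 5′ of the break on
the mapped strand (for minus-strand breaks, the reverse complement of
the plus-strand bases just downstream), then the first 50 read bases;
the break always sits between columns 50 and 51. Missing columns (short
reads, chromosome-edge breaks) are masked and excluded per column; a
read contributes to a pattern count only when all required columns are
unmasked, so chromosome-edge breaks drop out of before-break 4-mer
counts (negligible at 50-base edges of desk-scale genomes). Pattern
windows supported: 3+1, 4+0, 2+2, 4+1, 4+2, 6+0 and 6+2 bases
before/after the break; proportions are normalized by the reads
contributing to that window.

Genome-side 4-mer denominators count overlapping windows on the **plus
strand only** — the convention under which the genome margin of the
published 2×2 tables (C + D = 11 786 833 ≈ one strand of the yeast
assembly) is reproduced. Windows containing N are excluded from counts
but the 256-key set stays complete.

## Exact conditional inference

Conditioning a 2×2 table on both margins makes the A cell follow
Fisher's noncentral hypergeometric distribution with odds parameter ψ;
all point masses are computed in log space from log-gamma, so the
dominant table (margins ~1e3 × 1e7, p ≈ 1e−158) stays finite.

* **Two-sided p** — the sum of point probabilities not exceeding the
  observed one, with the classical 1e−7 relative tie tolerance.
* **Odds ratio** — the conditional MLE: the ψ solving E[A | ψ] = A on
  the monotone conditional mean. Zero at the bottom of the support,
  infinite at the top.
* **95 % CI** — central exact conditional bounds:
  P(X ≥ A | ψ_low) = 0.025 and P(X ≤ A | ψ_high) = 0.025.

Two solver conventions are exposed. `convention="reference"` (default)
replicates R `fisher.test` exactly: Brent's zeroin on the odds scale —
the reciprocal scale for roots above 1 — with the R-default absolute
tolerance `eps^0.25 ≈ 1.22e-4`. `convention="precise"` solves the same
equations to `xtol = 1e-12` on log ψ. For large odds ratios the two
differ visibly (the dominant table's reference estimate is 51.96 while
the precise score-equation root is 52.01): published tables from that
environment carry the reference tolerance, so the compatibility mode is
the default and the distinction is documented rather than silent. The
precise mode is cross-checked in the tests against
`scipy.stats.contingency.odds_ratio(kind="conditional")`, and the
two-sided p against exact-rational brute-force enumeration and
`scipy.stats.fisher_exact`.

Multiplicity is controlled with Benjamini–Hochberg across the 256
4-mer tests (via `statsmodels.stats.multitest`); rows are ranked by
adjusted then raw p, and significance is flagged at adjusted p < 0.05.
All 4-mers never observed before a break are additionally pooled into
one depletion table (A = 0, C = the sum of their genome counts); being
a single post-hoc test it is reported with its raw exact p, not
BH-adjusted.

## Sequence logos and positional nulls

Column information content is the plain `2 + Σ_b f_b log2 f_b` bits
(0·log 0 = 0), without a small-sample correction — matching the default
of the classical logo-plotting packages. The positional null resamples,
per chromosome, as many uniform positions (with replacement) as breaks
were observed there, assigns strands with the chromosome's observed
plus-strand proportion, and extracts the 100-base window placing the
sampled base at column 51, so observed and null breaks sit at the same
column boundary. Windows falling off a chromosome end are redrawn (and
counted), keeping every replicate's column coverage uniform. Logo
rendering (equal-height and IC-height) is a small matplotlib layer and
is only smoke-tested; the statistics live in the PFM/IC functions.

## Synthetic data: what it emulates and what it does not

`generate_genome` draws i.i.d. bases at the yeast composition
(A 30.9 %, C 19.2 %, G 19.1 %, T 30.8 %) over 16 chromosomes with
lengths proportional to the real karyotype (default total 50 kb — large
enough that ~2 000 retained reads and 256 tables are informative, small
enough that the full pipeline runs in seconds). `plant_breaks` draws
break positions with probability proportional to a per-4-mer weight
times that 4-mer's genome occurrence count, strands symmetric;
`motif_weight_for_fraction` inverts this to hit a target break fraction
(e.g. ~11.5 % of breaks after ACGT, the regime of the motivating
data). Reads are truncated to Normal(150, 30) bases (floored at 40,
Ion-Torrent-like); for First-linker products the truncation point is
clamped past the linker, since those reads are sequenced from the
First-linker primer and a read too short to cover its own linker is by
construction a type-5 artifact, not a type-1/3 product. Errors are
i.i.d. substitutions (no indels, no quality scores, no flow-space
model); the default product mix (16 / 7 / 4.8 / 6.8 / 65.4 %) mirrors
the gross screening ratios seen in real libraries and is a convenience
default, not a claim.

Two break-sampling regimes are provided. `"replacement"` (default)
lets several reads sequence the same break event, as PCR resampling of
a small break pool would; with ~2 000 reads over ~1 000 events this
clusters counts (~1.9 reads/event) and visibly inflates the exact
test's type-I error — a real property of resampled libraries, not a
bug. `"unique"` gives each break event at most one read, the regime of
a large cell population where break molecules vastly outnumber
sequenced products; under it the uniform-break null is exactly
multinomial and BH control holds (0 significant 4-mers in 10/10 test
seeds). Null-behaviour tests therefore plant one break event per
product and sample uniquely.

Because the genome is i.i.d., passing tests demonstrate correctness of
the screening/counting/statistics machinery — they do not demonstrate
robustness to real-genome features (repeats, chromatin-correlated break
rates, homopolymer sequencing errors). The BLAST import path exists for
real data; real-library-scale figures are outside the test surface.

## Numerical and degenerate-input choices

* Coordinates 0-based half-open internally; BED output matches;
  1-based only in human-readable column labels.
* `digest("" )` returns `[]`; a recognition site containing N never
  matches; fragment lengths always sum to the sequence length.
* Tables with degenerate margins (A+B = 0 or A+C = 0) raise rather
  than return a value; an all-zero read margin is rejected when tables
  are built.
* Identical-row tables return p = 1 exactly (the full support is
  "as extreme").
* Root brackets for ψ expand geometrically (factor 2 on log ψ, up to
  60 doublings) before Brent refinement.
* The 9/10 multi-map boundary is rejected by construction ("more than
  90 %" is strict).

## Known limitations

* The built-in mapper is exact-match; mismatch-tolerant mapping of
  error-bearing inserts requires the BLAST import path.
* Type 1 vs type 3 cannot be separated at classification time (both
  have intact linkers); they are separated by mappability downstream,
  and the class label "1/3" makes that explicit.
* The pooled depletion row's p-value is reported unadjusted (single
  post-hoc test); published analogues print the same number under an
  "adjusted" heading.
* Adjusted p-values of non-top rows depend on the full 256-vector of a
  given dataset; only the rank-1 adjustment (raw p × 256) is a stable
  cross-dataset anchor.
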