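# rindseq

Analysis toolkit for **ligation-mediated-PCR (LM-PCR) sequencing of
replication-independent endogenous DNA double-strand breaks
(RIND-EDSBs)** in resting *Saccharomyces cerevisiae* — and, with a
synthetic-library generator, for any organism-scale toy genome you care
to simulate.

In this assay a known *First linker* is ligated to each break end, the
DNA is digested with the blunt 4-cutter RsaI, a *Second linker* is
ligated to the cut end, and the region between linker primers is
amplified and sequenced. Every read that survives screening pins a
break: the first base of its genomic insert is the base immediately 3′
of a break. `rindseq` implements the whole downstream analysis:

1. **Linker screening** — local alignment of the linkers against each
   read and its reverse complement (match +1, mismatch −2, gap open −5,
   gap extension −2), classification into break-carrying products,
   truncated-primer artifacts, and Second-linker-only products, and
   retention of clean inserts longer than 10 bases with a gap- and
   mismatch-free First linker.
2. **Break mapping** — first-base-anchored mapping on both strands;
   multi-mapped reads are retained only when >90 % of their positions
   share the same preceding 4-mer.
3. **Stitched reads & catalog** — 100-column constructs (50 reference
   bases 5′ of the break + the first 50 read bases, break fixed between
   columns 50 and 51), a per-position break catalog, and the
   break-count vs chromosome-length Pearson correlation.
4. **Breakpoint k-mer statistics** — for every 4-mer *m*, a 2×2 table

   |                  | 4-mer = *m* | any other 4-mer |
   |------------------|------------:|----------------:|
   | stitched reads   | A           | B               |
   | genome positions | C           | D               |

   tested with a two-sided Fisher exact test computed in log space
   (finite p down to ~1e−160), Benjamini–Hochberg FDR across the 256
   tests, a **conditional-MLE odds ratio** (the ψ solving
   E[A | margins, ψ] = A under Fisher's noncentral hypergeometric
   distribution — not the cross-product AD/BC) with a central exact
   conditional 95 % CI, plus a pooled table of 4-mers never observed
   before a break.
5. **Sequence logos & positional nulls** — position frequency matrices,
   per-column information content (2 + Σ f log₂ f bits), and an
   empirical null that resamples break positions per chromosome with
   the observed strand mix.

A first-class **simulator** (`rindseq.simulate`) generates genomes with
a configurable base composition, plants breaks with configurable 4-mer
preferences, and emits all five LM-PCR product types (intact,
enzyme-fragment-only, chimeric with/without breaks, nonspecific
primer amplicons) with per-read ground truth, so the full pipeline is
testable offline.

## Worked example

```python
import rindseq as rs

genome = rs.generate_genome(16, rs.yeast_like_lengths(50_000), seed=1)
w = rs.motif_weight_for_fraction(genome, "ACGT", 0.115)
breaks = rs.plant_breaks(genome, 10_000, {"ACGT": w}, seed=2)
lib = rs.simulate_library(
    genome, breaks,
    params=rs.LibraryParams(n_products=10_000, seed=3, break_sampling="unique"))

result = rs.run_pipeline(lib.reads, genome)
print(result.class_counts)
print(result.association.summary(top=3))
```

prints (seed-exact):

```
{'1/3': 2053, '2/4': 1388, '5': 6559}
Breakpoint 4-mer association (exact conditional inference)
  stitched reads: 1977   genome 4-mer windows: 49951
  significant 4-mers (BH-adjusted p < 0.05): 1

  kmer     A         C      p_adj       OR           95% CI
  ACGT   273       181  1.61e-265    44.01 ( 36.12,  53.77)
  TAAT     6       441      0.496     0.34 (  0.12,   0.75)
  CTTC     1       181          1     0.14 (  0.00,   0.79)

pooled 4-mers never observed before a break:
  A=0 B=1977 C=156 D=49795  p=0.00498  OR=0.00 CI=(0.00, 0.60)

odds-ratio ranges: OR = 0: 2  0 < OR <= 1: 178  1 < OR <= 10: 75  OR > 10: 1
```

Reading the first row: 273 of 1 977 stitched reads carry `ACGT`
immediately 5′ of the break although only 181 of the 49 951 genome
4-mer windows are `ACGT`; breaks prefer `ACGT` ends with conditional
odds ratio ≈ 44 and an adjusted p ≈ 2e−265 — the planted signal,
recovered. No other 4-mer reaches significance. A `click` CLI exposes the same stages
(`rindseq simulate | trim | map | stitch | count | test | logo |
fragments`).

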