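# Methods

## Pre-processing

Reads are processed in a fixed order; each step's threshold is exposed in
`cladetrace.preprocess` with these defaults:

1. **UMI trim** — `umi_prefix_len` bases (default 0) are removed from the
   5′ end first, because protocols that carry a UMI prepend it before the
   insert and it would otherwise defeat adapter detection.
2. **Truncation** — everything beyond 50 nt is discarded. Inserts of
   interest (miRNAs, ~22 nt) sit well inside this window and the cap keeps
   per-read cost flat for long-read inputs.
3. **Quality filter** — a read is discarded when *more than* 50% of its
   bases have PHRED < 20. The inequality is strict: exactly half low is
   retained. Empty reads fail.
4. **Adapter trimming**, by protocol:
   * *TruSeq/QiaSeq*: search for the adapter's first 8-mer; cut at its
     **last** occurrence (an 8-mer inside the biological insert would
     otherwise truncate it). With no 8-mer hit, the longest read suffix
     equal to an adapter prefix (7→1 nt, minimum overlap 1) is trimmed,
     but the read counts as *adapter unrecognized* since the full 8-mer
     was never seen.
   * *NEXTflex*: 4 randomized protocol bases are dropped from the 5′ end,
     TruSeq trimming is applied, and when the adapter was found the last
     4 nt of the insert (the 3′ randomized bases) are dropped too.
   * *CATS*: 3 protocol bases are dropped from the 5′ end and the
     left-most poly-A 8-mer and everything after it is removed; failing
     that, progressively shorter trailing poly-A runs (down to one A).
5. **Ambiguity filter** — any non-ACGT symbol in the final insert
   discards the read. Filters are applied to the final insert (the order
   relative to partial-adapter trimming is a design choice; an N inside a
   trimmed-away adapter should not kill the read).
6. **Complexity filter** — an insert that is a tandem repeat (truncated
   final unit allowed) of a single 1-, 2- or 3-nt motif is discarded.
   "Highly repeated" is deliberately concretized this way and the
   predicate is pluggable (`preprocess_read(complexity_filter=...)`).
7. **Length** — inserts < 18 nt are discarded as too short, whether or
   not an adapter was found: a shorter insert cannot be matched reliably.
   Reads ≥ 18 nt survive as *QC-passed* — `adapter_found` or
   `adapter_unrecognized`.

The conservation identity `input = passed(found) + passed(unrecognized) +
Σ discards` holds per sample and is asserted in the tests.

## RNA-type annotation

QC-passed reads are matched as ungapped substrings (no indels; Hamming
mismatches only) against ordered collections: miRNA precursors, then
tRNA, then rRNA. Pass 1 allows 0 mismatches across all three
collections; only if it fails entirely does pass 2 rerun the same
priority with 1 mismatch — so an exact rRNA hit beats a 1-mismatch
precursor hit, and the joint (not per-database-interleaved) reading of
the two passes is a documented choice. Reads still unmatched are
compared against sequencing-artifact sequences, requiring a shared 18-mer
("18 nt stretch of identity"); the rest are `unknown`. Ties within a
collection resolve to the lexicographically smallest reference ID —
determinism matters, the type is what gets reported. The 1-mismatch
search is pigeonhole-seeded (one half of the read must match exactly),
which the tests check against a brute-force all-offsets oracle.

The complexity curve records, at every `checkpoint_step` raw reads
(default 10,000 — plotting granularity) and at end of stream, the
cumulative number of distinct precursor IDs hit by miRNA-annotated
reads. Depth counts *raw* reads, including discarded ones, so curves are
comparable across samples of different quality.

## Marker catalog and tracing

The catalog maps miRNA family numbers (with `let-7`-style names in a
separate namespace from `miR` numbers) to clades; mature sequences whose
parsed family number is listed are admitted. In **clade mode** every
20-nt window of an admitted sequence is indexed; in **species mode**
only the first 20 nt (prefix-to-prefix matching, for curated
species-specific catalogs). Indexing all windows in clade mode is the
permissive reading of "first 20 nt of the read matches the reference";
the prefix-only behavior is available as species mode. A 20-mer found in
two clades is excluded from the index and surfaced in an ambiguity
report rather than multi-assigned — markers must be clade-exclusive, and
the report lets catalog curators fix the source. Matching is
strand-specific: small RNAs are sequenced sense.

A read is assigned by looking up its first 20 nt; composition
percentages use clade-specific reads as denominator. `min_reads` for
contamination reporting defaults to 1: single-digit foreign read counts
are already informative at this specificity.

### Specificity model

A uniform-random read's leading 20-mer hits a W-key index with
probability `1 − (1 − 4⁻²⁰)^W`; the expected spurious-match count among
N reads is N times that (≈ N·W/4⁻²⁰ ≈ N·W/1.1·10¹²). W counts
*distinct* indexed 20-mers. The Monte-Carlo check bit-packs 20-mers into
40-bit integers and draws uniform integers, so 10⁷ draws run in seconds;
the analytic value and the simulation are compared under a Poisson 3σ
band in the acceptance test.

## QC flags

* `length_flag`: < 25% of the sequences in the length panel are 20–25 nt.
* `mirna_content_flag`: miRNA-annotated reads < 10% of QC-passed reads.
* `complexity_flag`: distinct precursors seen < 10% of the species'
  known precursors.

All inequalities strict. The length panel includes every read that
survived the quality filter — zero-length entries (adapter dimers) and
discarded short/ambiguous/low-complexity inserts are shown, because that
is what makes degraded libraries visually diagnosable; the panel
therefore sums to more than the QC-passed count when such discards
exist, and the length-flag fraction uses the panel total as denominator.

## Contamination cleaning

Three demultiplexing regimes of strictly increasing stringency (the kept
read set of each is a subset of the previous, asserted as a property):
`mismatch1` (exactly one sample index within Hamming distance 1; pairs
of configured indices closer than distance 3 draw a warning), `strict`
(perfect matches), and `strict_consistent` (perfect match plus, when
readable, agreement with the inline index — the copy of the index that
the main read carries after the full 3′ adapter). The full adapter, not
just its 8-mer, must be present before the inline index is trusted, so
insert bases are never read as index; the comparison is exact, with N a
mismatch. Reads whose inline index is unreadable (adapter truncated or
absent) are **retained** by default — consistent with cleaning being
total in only some samples in practice — and dropped with
`--drop-unverifiable`. Retained reads are written byte-identical.

## Synthetic data

The generator states one world and keeps it: 75-cycle single-end reads
(so a 22-nt insert + 33-nt TruSeq adapter + 6-nt index = 61 nt leaves
the inline index readable), insert lengths peaked at 22 nt
({20: 0.1, 21: 0.2, 22: 0.7} — truncations of the 22-nt markers),
PHRED ~ N(36, 3) clipped to [2, 41], 0.1% substitution-only sequencing
error (no indels, matching the pipeline's ungapped model), TruSeq-style
6-nt indices with pairwise Hamming ≥ 3. The default reference bundle has
14 clades × 24 families × 4 species at 22 nt ≈ 30,000 reference nt, the
scale of a curated clade-marker catalog; families are sequence-identical
across their species (miRNA conservation), and rejection sampling
guarantees no 20-mer is shared between clades, so error-free reads trace
exactly. Spike-in counts are `round(fraction · total)`: at fraction
10⁻⁵ of 10⁶ reads that is 10 contaminant reads.

What the generator does **not** emulate: realistic Illumina error
profiles (quality-correlated, position-dependent), PCR duplicates,
expression-abundance skew between miRNA families, isomiR end-variation
beyond simple truncation, and annotation imbalance between clades. A
green test on this substrate establishes the algorithmic contracts
(trimming recovers known inserts, markers trace to their clade,
corrupted indices are removed), not performance on real libraries —
real-data accuracy additionally depends on catalog curation, which is
out of scope here.

## Numerical and degenerate-input choices

* PHRED offset 33 by default, 64 selectable; negative decoded scores are
  a hard parse error (wrong offset).
* Empty FASTQ → empty stream; empty quality-filter input → read fails.
* Zero clade-specific reads → contamination report returns a
  "no evidence" flag rather than an empty-but-confident report.
* Undefined confusion-matrix ratios (zero denominators) are `None`,
  never 0 or 1.
* RPM requires a positive total; differential calls use the printed
  strict bounds (≥ 10 RPM, fold > 2) with no pseudocount — absence is
  handled by the explicit single-sample rule.
* All generation and catalog construction is order-independent and
  seed-deterministic; shuffled inputs give identical indexes.

## Known limitations

* Clade abundances are *not* corrected for unequal marker-set sizes or
  expression levels between clades; relative abundances across clades
  can be skewed even when detection is correct.
* Per-miRNA expression quantification is out of scope; the RPM/DE
  helpers implement bookkeeping for externally produced count tables.
* Error-tolerant adapter alignment is deliberately absent: the trimmer
  is exact-8-mer based, so an adapter whose first 8-mer is misread
  leaves the read adapter-unrecognized.
* Dual-index chemistry and BCL-level demultiplexing are not handled; the
  cleaner works on single 6–8-nt indices in headers or index FASTQs.
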