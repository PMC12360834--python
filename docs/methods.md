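# Methods

This note records the model behind `bishash`, the parameters that
matter, the numerical conventions, and the design choices made where
the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Multi-metric MinHash

**Model.** A sequence is represented by the set of its distinct
k-mers over {A,C,G,T}; windows containing any other letter are
dropped (no IUPAC expansion — standard sketching practice). A
*metric* here is a letter-collapse equivalence on k-mers: identity,
C≈T (`C→T` image) or G≈A (`G→A` image). Collapse maps are idempotent
and the identity refines both collapses.

The k-mer universe is partitioned into `z = 3^κ` cells by the first κ
letters read in the three-letter alphabet of the conversion direction
(CT direction: digits A=0, G=1, C/T=2; GA direction: C=0, T=1,
G/A=2 — the digit assignment is an arbitrary but fixed convention,
recorded so serialized indexes are portable; cell *labels* never
affect votes or scores). Reading the prefix in the merged alphabet
guarantees a bisulfite conversion cannot move a k-mer between cells.

The sketch is a `(z, Δ, R)` grid: entry (i, j, r) is the minimum over
cell *i*'s k-mers of a seeded 64-bit hash of the metric-*j* collapsed
k-mer. Hashing the collapsed representative makes the hash constant
on metric classes, which is the property the whole construction rests
on. `R` independent seeded repetitions per (cell, metric) realize the
classic "η hash functions" of MinHash and reduce estimator variance;
the default `R = 4` keeps the index small while giving
`z·Δ·R = 72` vote coordinates per read.

**Comparison.** For each (cell, repetition), the match indicator is 1
when at least one metric's minima agree, or when the cell is empty in
*both* sets; one-sided emptiness is a non-match. The mean indicator
Ξs estimates the multi-metric Jaccard similarity JSIM. Two
conventions deserve note:

- The metric-mediated intersection `(A∩ζᵢ) ∩_d (B∩ζᵢ)` is computed as
  the members of `A∩ζᵢ` whose collapsed image occurs among the
  collapsed members of `B∩ζᵢ`. This makes JSIM computable; it is
  asymmetric in principle (it counts A's members, not equivalence
  classes), and the relationship between Ξs and JSIM is therefore
  *verified empirically* in the acceptance suite rather than assumed:
  the mean Ξs is checked against the closed form
  `(1/z)·Σᵢ[1 − Πⱼ(1 − J(c_j(Aᵢ), c_j(Bᵢ)))]`, which is the exact
  expectation because repetition seeds are independent across
  metrics. The step equating that product form with `E[max_j …]` is
  not an identity in general; it is not relied on anywhere in the
  code.
- Because the max over per-cell metric assignments decomposes cell by
  cell, JSIM is computed per cell and summed; an exhaustive `Δ^z`
  oracle must agree exactly (tested for z ≤ 3, Δ ≤ 3).

**Hashing.** A splitmix64-style avalanche mixer over the 2-bit-packed
collapsed k-mer, seeded per (metric, repetition) by fixed arithmetic
on a single 64-bit master seed. Any avalanche-quality mixer would do;
this one is dependency-free and vectorizes. The all-ones 64-bit value
is reserved as the UNDEFINED (empty cell) sentinel; a hash landing on
it is clamped to the adjacent value.

## Segmentation and the vote index

The genome is cut into segments of length `T` (default 500 bp)
stepping by `T − τ` with overlap `τ` (default 300 bp, which must be at
least the maximum read length — alignment rejects longer reads with a
clear error). The final segment is anchored to the contig end so
every τ-length window is contained in at least one segment; contigs
shorter than `T` become one whole-contig segment. `T` comparable to a
few read lengths keeps per-segment k-mer sets small enough that a
150 bp read retains a usable per-cell Jaccard against its segment.

Each segment is sketched twice — once per conversion direction, each
with metric family (identity, that direction's collapse) and that
direction's partition alphabet (the re-partition under the GA alphabet
is symmetric with the CT construction) — and every defined sketch
entry is inserted into an ordered map keyed by (cell, metric,
repetition, value). A read's sketch entries are looked up and
per-segment vote counts accumulated; segments with votes ≥
max(`min_votes`, ⌈`fraction` · best⌉) are kept, best first, capped at
`max_candidates` (defaults 2 / 0.8 / 10, all CLI-configurable). With
72 coordinates the vote counts are noisy, which motivates the padded
extension window below.

The on-disk index stores a JSON parameter header, the contig
sequences, and per mode the sorted key/payload arrays (little-endian;
layout documented in `index.py`). Loading reproduces queries
bit-for-bit.

## Alignment

**Strand protocol.** Directional-library convention: the read as-is
is sketched against the CT index and extended with the CT scheme; the
reverse-complemented read against the GA index with the GA scheme.
This matches where G→A appearance on the forward reference comes
from. Non-directional (PBAT) libraries are a flagged extension, not
implemented.

**Scoring.** Affine-gap local alignment (Smith–Waterman recurrences)
with defaults match +2, mismatch −3, gap open −5 (score of a gap's
first base), gap extend −2. The bisulfite asymmetry enters only
through the substitution function: in CT mode (genomic C, read T)
scores *exactly like a match* — interpreting the "no penalty"
principle as full match reward, since a literal zero would
systematically penalize heavily converted reads against unconverted
ones — while (genomic T, read C) stays a mismatch; GA mode mirrors
this. Asymmetric matches are reported as CIGAR `M`.

**Determinism.** Traceback prefers diagonal, then deletion, then
insertion; within a gap, ties end the gap; the reported cell is the
first maximum in row-major order. Candidate ties break by score, then
contig order, then position. The DP is full (non-banded) over
read × window for exactness; the kernel is JIT-compiled (numba) and
releases the GIL, so the optional thread pool scales while output
order — and hence SAM bytes — stays independent of worker count.

**Extension window.** Candidates are aligned not against the bare
segment but against the segment padded by one read length on each
side (clipped at contig ends). Vote counts over 72 coordinates are
noisy enough that the unique fully-containing segment occasionally
falls below the candidate threshold while an overlapping neighbour
passes; the padding lets a read straddling the voted segment's
boundary still align in full, and hits reached through different
overlapping segments deduplicate by their genomic position.

**Reporting.** Best alignment per read as SAM (FLAG 16 + reverse-
complemented SEQ for GA-mode hits; FLAG 4 for unmapped), with tags AS
(score), XC (candidate count), XM (CT/GA). Reads are unmapped when no
candidate passes the vote rule or the best score falls below
`min_score_fraction` (default 0.66) of the perfect score
`match · read_length`. MAPQ is a non-standard surrogate:
0 when the two best distinct positions tie, else
min(60, 4·(best − second best)). Only the primary alignment is
emitted; XC records ambiguity.

## Simulator

The simulator emulates the experimental factors of a directional
bisulfite protocol at desk scale, not any particular read-simulation
tool. Reference contigs are i.i.d. at the target GC (so dinucleotide
frequencies factorize when island density is 0), with optional
CpG-enriched islands (CG-dinucleotide emission probability 0.35,
island GC 0.6, lengths 300–1000 bp) covering a chosen fraction of the
contig.

Methylation landscapes:

- **normal** — CpG cytosines 0.8, CpG cytosines inside islands 0.2,
  non-CpG cytosines 0.02. These defaults follow the qualitative
  biology (isolated CpGs hypermethylated, island CpGs hypomethylated,
  non-CpG contexts nearly unmethylated); they are assumptions, not
  reproductions of any measured landscape. Islands are *detected*
  from local CpG density (≥ 0.15 CG starts/bp in a 201 bp window),
  keeping the profile self-contained for arbitrary references.
- **random** — every cytosine-context probability i.i.d. Uniform(0,1),
  the unpredictable landscape used to stress aligners.

Guanine positions carry the mirrored track for bottom-strand
cytosines. Reads draw uniform (contig, offset, strand); each C (resp.
G on the bottom strand) converts with probability 1 − m; uniform
substitution errors (default 1%; the error model is deliberately
simple — no indel errors by default, no quality profile) are applied
last; base qualities are constant 'I' and ignored by the aligner.
Truth records carry contig, 0-based start, strand, and conversion/
error counts.

**What passing tests do not show.** The simulator has no adapter
contamination, PCR duplicates, quality-dependent errors, repeats
beyond what an i.i.d. genome contains, or incomplete-conversion
artifacts; accuracy on it upper-bounds, rather than predicts,
accuracy on real libraries and real (repeat-rich) genomes.

## Evaluation

A mapped read is correct when the contig matches and the reported
leftmost position is within `tolerance_bp` (default 1) of the
simulated 0-based start; strand agreement is optional
(`--require-strand`). SAM positions are handled through pysam, which
resolves the classic 1-based/0-based trap; fixtures exercise both
directions. FDR = incorrect / mapped, defined 0 when nothing maps.
Percent-correct is reported against both denominators (all reads and
mapped reads), since either convention is defensible.

The dominant residual error mode at 1% substitution error is
positional, not a mismapping: an error at the read's second base
makes a 2-base soft clip score-optimal (+2·2−3 < 2·2), shifting the
reported start by 2 bp — just outside the 1 bp tolerance. This
affects roughly the fraction of reads carrying an error at that
specific offset and bounds attainable percent-correct below 100 even
with perfect candidate selection.

## Problem sizes

The acceptance study uses a 200 kb single-contig genome with 2000
reads of 150 bp from both strands — large enough that segments
(~1000) and votes behave as in a production setting while the whole
pipeline, including JIT compilation, completes in tens of seconds on
one CPU. Sketch-estimator checks use 2000 seeded repetitions, the
scale at which binomial standard errors are tight enough to detect
bias. Guarantee-style parameters of the underlying hashing framework
(similarity thresholds σ/δ and probability bounds p₁/p₂) have no
runtime role and appear only in this documentation and the property
tests.

## Known limitations

- Single-end, directional libraries only; no paired-end mating, no
  PBAT.
- No methylation calling — the aligner stops at positions; β-values
  are downstream.
- Full DP over padded segments is exact but quadratic; a band is the
  obvious performance lever, deliberately off by default.
- MAPQ is a surrogate, not calibrated to error probability.
- The candidate vote threshold trades recall for extension work; on
  repeat-rich genomes `--fraction`/`--max-candidates` may need
  loosening.
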