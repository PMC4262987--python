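# Methods

## Scope and model

coremum aligns the *core* genome — sequence present orthologously in
every input — of closely related microbial assemblies. Subset
relationships (sequence shared by only some genomes) are deliberately
out of scope: anchors must be present exactly once in *every* genome.
The method assumes intraspecific input (≥~97% ANI); far below that,
multi-MUM anchors become sparse and the core collapses.

## Coordinates, alphabet, contigs

All internal coordinates are 0-based half-open; exporters convert to
1-based where the format demands it (XMFA, VCF). Sequences are
uppercased and every non-ACGT character becomes N. N never matches
anything, including another N: in the suffix-array encoding every N
(and every contig separator and terminator) receives a globally unique
integer code, so matches can neither include ambiguous bases nor cross
contig joins. Draft assemblies are concatenated contig-by-contig with
one separator per junction; matching works on the concatenation, and
positions map back to (contig, offset) via the offset table.

## Match finding

The match engine builds one enhanced suffix array (prefix-doubling
construction, Kasai LCP; a numba-compiled LCP kernel is used for large
inputs when available, with a pure-Python fallback producing identical
output) over the forward and reverse-complement copies of all g
sequences. A window of g consecutive suffix-array entries is a
multi-MUM exactly when (i) its inner LCP minimum L ≥ the minimum
length, (ii) both boundary LCPs are < L (uniqueness), (iii) the g
suffixes come from g distinct genomes (presence exactly once each,
counting both strands), and (iv) the preceding characters are not all
equal (left-maximality; right-maximality follows from L being the
inner minimum). Each match appears once per strand of its substring;
the copy with the reference forward is kept. With g = 2 the same scan
yields classical pairwise MUMs for streaming queries and for MUMi.

Overlapping multi-MUMs are trimmed to non-overlapping reference
extents, longest first, ties to the leftmost; the trailing fragment of
a trimmed anchor is kept whatever its length, since chaining and
weight filtering decide its fate.

Correctness is checked against a brute-force oracle (substring
containment + overlap-aware counting on plain strings) on random
instances up to 5 genomes × 2 kb, exact set equality.

### Recursive refinement

Between each pair of reference-consecutive anchors that is consistent
in every genome (same orientation, non-negative gaps ≤ `max_gap`,
disparity ≤ `max_diag_diff`), the region's per-genome sequences are
re-scanned with the minimum length halved per level, never below
`refine_floor` (default 12; the initial length is 21, so one extra
level runs at 12). Uniqueness inside a region is region-scoped.
Sub-anchors are kept only if forward and collinear in all genomes
(greedy by region position); the recursion then descends into the
remaining sub-gaps.

### Partitioned search

`--max-partition-size` bounds the number of genomes per suffix-array
scan: multi-MUMs are computed per batch against the shared reference
and intersected on reference coordinates. Fragments inherit their
placements from the batch anchors; each fragment's substring is
re-verified to occur exactly once in every genome (both strands), and
contiguous fragments are re-merged. The intersection can split
anchors, never extend them.

## MUMi recruitment

MUMi = 1 − L_mum / L_av over pairwise MUMs at minimum length 19, both
orientations counted, with greedy longest-first trimming to
non-overlapping coverage *on both genomes* (the tie-break key is
symmetric in the pair, so the distance is symmetric). The default
recruitment threshold 0.3 is deliberately permissive: genomes at the
~97% ANI species boundary can share well under half their length in
long exact matches. `--force-all` recruits everything but still
reports distances.

## Chaining and the diagonal-difference rule

Chaining is greedy in reference order: an anchor extends the current
chain iff order and orientation are consistent in every genome, every
inter-anchor gap is in [0, `max_gap` = 10 kb], and the gap lengths
across genomes differ by at most `max_diag_diff` = 100 bp. The last
rule is this package's own design choice beyond plain collinearity:
without it a ~1 kb insertion in a single genome (e.g. a translocated
segment's landing site) is absorbed into the chain, producing a ~1 kb
block of indel columns that (a) bloats the alignment, (b) hides the
insertion junction from the LCB table, and (c) occasionally seeds
misaligned full columns — the only false-positive SNP source observed
during development. With the rule, such junctions break chains and the
affected sequence is still aligned where it is actually orthologous.
100 bp is intentionally larger than any gap-length disparity that
substitution noise can produce (zero, absent indels) yet far below
rearrangement scale; real small indels pass freely.

`min_lcb_weight` defaults to 3× the minimum anchor length (63). The
weight filter never discards data: dropped blocks stay in the archive
and their columns carry the `LCB` flag.

## Gap alignment

Distinct gap sequences are collapsed before alignment (a block with 30
identical gaps and one variant costs one pairwise alignment), aligned
progressively longest-first (ties by the smallest carrier genome id),
and re-expanded. Pairwise steps use Biopython's PairwiseAligner with
match +5, mismatch −4, gap open −12, extend −1 (a length-k gap costs
−12 − (k−1)); an independent textbook Gotoh oracle in the test suite
checks the scores. Later sequences join via a profile-to-sequence
Gotoh step with mean-of-pairs column scoring (gap characters score −1
against a residue) and a fixed tie order (substitution > gap column in
profile > gap in sequence). Joins whose DP table would exceed 5·10⁵
cells fall back to pairwise alignment against the profile's guide row
with gap-column propagation — quadratic profile DP in Python is the
one place raw size matters. Degenerate cases short-circuit: all gaps
empty, all identical, or exactly one non-empty.

Every aligned block is validated by the degap-reconstruction identity:
removing gaps from any row must reproduce the genome's substring over
the block extent exactly (reverse-complemented for reverse-orientation
genomes). Failure is a fatal internal error, not a warning. Gap blocks
are independent, so thread-parallel alignment is bit-identical to
serial; the thread count only changes wall time.

## Variant filtering

All polymorphic columns (≥2 distinct non-N alleles) are extracted with
per-genome positions tracked during a single walk of each block. Flags:

* `REP` — the reference position is covered by a k-mer (default k=21,
  odd, so no reverse-complement palindromes) occurring more than once
  in the reference counting both strands.
* `LCB` — column originates from a weight-dropped block.
* `ALN` — the window of 100 alignment columns centred on the column
  contains more than 10 variant columns (SNPs and indel columns count
  together). This is the misalignment guard near rearrangement
  junctions.
* `QUAL` — reserved for read-based base-quality evidence; the flag is
  defined in the VCF header and never set, keeping downstream formats
  stable for pipelines that do have read data.
* `REC` — pairwise homoplasy (PHI) permutation test, computed
  natively. Sites with missing data are excluded; remaining sites are
  binarized major/minor (ties to the lexicographically smallest base);
  singleton sites cannot violate the four-gamete condition and are
  skipped. The statistic is the mean incompatibility over site pairs
  within `phi_window` (default 1000) alignment columns of each other;
  the null distribution permutes the assignment of allele patterns to
  site positions (default 1000 permutations, seeded), and
  p = (1 + #{PHI_perm ≤ PHI_obs}) / (n+1). When no pattern pair is
  incompatible at all — the clonal case — the test short-circuits to
  p = 1 without permuting. On significance (p ≤ 0.05) `REC` is set on
  every variant column spanned by an observed incompatible pair, which
  localizes the flags to the recombinant tract.

Core SNPs are the columns with no flags, no gap allele and no N. The
filters are monotone (they only remove columns) and idempotent (the
permutation is seeded).

## Phylogeny

p-distances over core SNP columns where both alleles are non-N,
Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3). Because columns are
restricted to polymorphic sites, p can legitimately approach 1 when
few genomes or columns are available; p ≥ 0.75 raises a saturation
error and the pipeline then reports the run without a tree rather than
failing. Neighbor joining is implemented natively with deterministic
tie-breaking (smallest Q; ties by the lexicographically smallest pair
of subtree labels, each subtree labelled by its smallest leaf) and
negative branch lengths clamped to zero with the deficit moved to the
sibling. Trees are unrooted, children canonically ordered by smallest
descendant leaf, branch lengths serialized at 6 significant digits.
An external tree tool can replace this step by operating on the
exported SNP-FASTA; all I/O contracts stay the same.

## Archive format

A 16-byte header (`CGAR`, version, endianness tag) followed by
zlib-compressed, CRC-32-checked, length-prefixed sections in fixed
order: reference (metadata + sequence), genome table (ids, lengths,
contig tables, md5 of each concatenation), annotations, LCB table,
variants, Newick tree, run config. The LCB table stores each block's
segment layout (anchor/gap lengths) plus per-genome extents delta-
encoded against the previous block end (LEB128/zigzag varints) and
orientation bits; the variant section stores 4-bit-packed alleles.
Reconstruction needs no genome sequences: inside a block, a column is
an anchor column (all rows = reference), a recorded variant column
(rows = stored alleles), or a monomorphic gap column (all rows =
reference base); the reference pointer advances except across
reference-gap variant columns. The XMFA writer is shared between the
live pipeline and archive reconstruction, making the bit-exactness
guarantee structural rather than coincidental. Corruption anywhere
fails loudly with the section name; version mismatches are explicit
errors.

## Simulator

The generator emulates the closed-genome benchmark protocol: a random
ancestor (default 100 kb, GC 0.5, optional planted repeat segments)
evolves along a balanced binary tree (default 32 leaves) at a
configurable substitution rate per site per branch; substitutions are
binomial over sites with transitions favoured tstv : 1 (default 4, the
expected transition:transversion *count* ratio); no indels are
introduced. Each leaf then receives Poisson(10) rearrangements —
inversions and translocations with equal probability, sizes
Normal(1000, 100) bp, non-overlapping in ancestor coordinates;
translocation re-inserts the segment at a uniform position outside any
rearranged segment. Sizes are kept narrowly around the mean
deliberately: the protocol describes "~1 kb" events, and a heavy
lower tail (e.g. geometric) creates sub-100 bp segments that no
anchoring method can delimit, which measures the size distribution
rather than the aligner. Everything is reproducible from one seed.

What the simulator does *not* emulate: indels, rate heterogeneity
across sites, base-composition skew, sequencing/assembly error, and
the repeat structure of real genomes (unless repeats are explicitly
planted). Passing benchmarks on this generator therefore demonstrate
coordinate bookkeeping, anchoring, chaining and filter behaviour — not
robustness to assembly artifacts or real repeat families.

### Benchmark scale and what it does to sensitivity

Desk-scale runs use a 100 kb ancestor in place of a multi-Mb genome
while keeping **10 rearrangements per genome**. With 32 genomes this
plants ~800 breakpoints on 100 kb — one per ~125 bp, a ~46× higher
breakpoint density than the same protocol on a 4.6 Mb genome. Core
coverage, not calling accuracy, then dominates sensitivity: every
breakpoint costs a few unanchored bases at each flank, and blocks
shorter than the weight threshold are flagged out entirely. At this
density the pipeline measures TPR ≈ 0.49–0.73 across rates
(fixed seeds) with **zero false positives**, versus ≥0.99 sensitivity
reported for the same method at full genome scale where the identical
per-genome rearrangement load shreds only ~7% of the sequence. The
breakpoint-recovery and specificity results are scale-robust; absolute
TPR at desk scale is not, and the acceptance suite records this
honestly rather than re-tuning the study conditions.

## Numerical and determinism notes

* All randomness (simulator, PHI permutations) flows from explicit
  seeds; identical configs give byte-identical outputs.
* Anchor trimming, chaining, guide order, NJ tie-breaks and traceback
  preferences are all fixed deterministic orders.
* The suffix-array scan is limited to 62 sequences per call (bitmask
  width); larger runs go through the partitioning path.
* Saturated distances (p ≥ 0.75), all-N references, empty cores and
  archive corruption raise typed exceptions; the CLI maps input errors
  and empty-core errors to distinct exit codes (2 and 3).

## Reference invariance

The multi-MUM set is symmetric in the genomes by construction (one
generalized scan, canonical orientation aside), so the choice of
reference does not change which columns are core on collinear input:
the core SNP allele matrix, re-keyed to any fixed genome's
coordinates, is identical across reference choices, and the test suite
asserts exact equality for three different references. Around
rearrangement breakpoints the guarantee weakens at block *termini*:
anchor trimming and greedy chaining operate in reference coordinates,
so the last few bases of an LCB can enter the core under one reference
and fall just outside it under another. Shared columns still agree
allele for allele; only boundary-adjacent column membership can
differ, by a few bases per breakpoint.

## Known limitations

* No LCB extension beyond terminal anchors: sequence between the last
  anchor of one block and the first of the next is not aligned.
* No subset (accessory) alignment, bootstrap support, or base-quality
  (`QUAL`) evidence.
* The gap aligner is built for short gaps; very long near-identical
  gaps fall back to guide-row joins rather than full profile DP.
* MUMi on heavily repetitive genomes underestimates shared content
  (repeat copies are never unique matches).
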