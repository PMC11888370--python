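# Methods

This note records the models, algorithms, parameter choices and
limitations behind `delkit`, in the order a read travels through the
pipeline.

## Error-correcting barcodes over GF(4)

DNA's four-letter alphabet maps naturally onto the four-element field
GF(4); we fix A=0, C=1, G=2 (ω), T=3 (ω²), with addition = XOR on the
2-bit encoding and multiplication by table. A barcode set is a subset of
a linear code over GF(4), so the minimum pairwise Hamming distance of any
subset equals at least the code's minimum distance.

**Distance-3 codes (default).** The parity-check matrix H of the full
quaternary Hamming code of redundancy 3 has as columns the 21 projective
points of PG(2, 4) (representatives with first nonzero coordinate 1,
sorted lexicographically). Shortening to length *n* ∈ [7, 16] keeps the
first *n* columns, giving an [n, n−3] code: no column is zero or a scalar
multiple of another, hence minimum distance 3 and unique syndrome
decoding of every single substitution. The certificate ("no two columns
projectively equal") is re-verified at construction.

**Distance-4 codes (parity mode).** Appending an overall-parity row and
symbol to a shortened GF(4) Hamming code — the textbook binary recipe —
does **not** reliably reach distance 4 over GF(4): a weight-3 codeword
whose symbols sum to zero survives extension at weight 3. We instead take
H's columns from an elliptic quadric (ovoid) in PG(3, 4): the 17 points
of x₀x₁ + x₂² + x₂x₃ + ωx₃² = 0 contain no three collinear points, so any
*n* ≤ 16 of them give an [n, n−4] code of certified minimum distance 4
(every 3 columns linearly independent — verified exhaustively at build
time, ~560 triples). Distance 4 corrects one substitution and guarantees
that two substitutions are never silently miscorrected
(`detected_uncorrectable`).

Syndrome decoding is a hash lookup over the 3n (or 4n) single-error
syndromes α·H[:,j]. In non-parity mode an unmatched nonzero syndrome is
reported `invalid` (shortened codes leave unused syndromes); distance 3
cannot distinguish double errors, so `detected_uncorrectable` is reserved
for parity mode. Barcode sets are sampled from the codebook without
replacement using a seeded generator; no GC-content or homopolymer
filtering is applied. The hash-map lookup decoder for unstructured tag
sets corrects a single-substitution neighbour only when exactly one tag
claims it and the neighbour is not itself a tag; ambiguous neighbours are
invalid. On a tag set that *is* a codebook subset it provably agrees with
syndrome decoding, and a test asserts this.

## Configuration

Libraries are JSON (ordered section list, so barcode layout is explicit),
building blocks CSV/TSV (`id`, `tag`, optional `smiles`; header row;
delimiter by extension), selections YAML. All paths resolve relative to
the defining file. In `hamming` mode every tag is checked to be a
codeword of the deterministic (length, parity) code at load time. Key
typos and unknown library ids get a nearest-name suggestion at
Levenshtein distance ≤ 2 (ties lexicographic) — close enough to be
useful, far enough to avoid absurd suggestions. Sample-index barcodes can
be declared as schema sections but demultiplexing by index is left to
upstream basecalling, which is where it normally happens.

## Semi-global alignment

Both demultiplexing and schema mapping use the same aligner: the pattern
must align end to end, read overhangs are free (adapter-style semi-global
mode). Scoring: match +1, mismatch −1, first gap base −2, each further
base −1; a wildcard (`N`) pattern position scores 0 against anything, so
tag/UMI regions neither attract nor repel the alignment and the constant
regions do the anchoring. These values are this package's own defaults;
they are deliberately ordinary.

The Gotoh three-matrix recursion is vectorised row-wise over the pattern
with numpy; the within-row affine gap recurrence collapses to a running
prefix maximum (`Ix[i,j] = max_{j'<j} M[i,j'] + open + (j−j'−1)·extend`,
computed with `maximum.accumulate`). Scores are integers, so traceback
reconstructs the optimal path by exact score comparison, preferring
diagonal moves, then read-gaps; final-score ties resolve to the leftmost
read end. Errors = substitutions at non-wildcard positions + inserted +
deleted bases; a hit is rejected when errors/|pattern| exceeds the
configured tolerance (default 0.1 for both the library-tag and schema
stages). Correctness is checked against an independently written
plain-Python DP oracle on 1,000+ random (read, pattern) pairs.

## Decoding pipeline

Per read, stages run in order and the first failure is the read's
categorical outcome (`no_library_match`, `schema_align_failed`,
`bb_tag_invalid` with the failing cycle, `umi_missing`), so outcome
counts always sum to the input read count. Both orientations are tried
(long-read amplicons arrive in either direction) and the better
library-tag alignment picks the strand. Two fast paths keep throughput
up without changing semantics: an exact regex match of the full schema
(constants literal, variable sections `[ACGT]{L}`) short-circuits both
alignments, and an exact substring hit of the library tag skips the
stage-1 DP. Tag calling requires the extracted span to have the tag's
exact length (an indel inside a tag is a flagged failure, not a guess);
a Hamming correction landing on a codeword the library does not use is
likewise invalid.

UMI-corrected counts deduplicate PCR copies: the count is the number of
distinct UMIs (`exact`, default) or of greedy clusters merging UMIs
within Hamming distance 1 in descending-count order (`cluster1`, for
error-prone UMIs). State is a mergeable structure (raw tallies + UMI
multisets); merge = sum + multiset-union is associative and commutative,
so any sharding of the read stream reproduces single-pass results
bit-identically — decoding parallelises by splitting FASTQs, with
orchestration left to the caller. The cube CSV is sorted by compound id
with LF endings, hence byte-deterministic.

## Enumeration

The reaction scheme is a linear list of two-reactant SMIRKS transforms:
step *i* couples the running intermediate (seeded with cycle 1's block)
to cycle *i+1*'s block; `identity` is a no-op placeholder. Nonlinear or
conditional schemes are rejected up front. When RDKit returns several
products, the first by canonical-SMILES rank is kept and a warning
logged — deterministic output with visible diagnostics. A block that
cannot react yields an in-stream failure marker, so batch enumeration
always yields exactly ∏|cycles| records; a block with *no* structure is
a configuration error instead. Compounds are enumerated off-DNA; the
attachment point is not modelled.

## Enrichment statistics

Formulas (UMI counts by default; raw counts optional):

- sampling depth = total reads / library diversity;
- NSC = count × 10⁶ / condition total (counts per million);
- z = (c − n·p₀)/√(n·p₀(1−p₀)) with p₀ = 1/|library| (one-proportion),
  or the pooled two-proportion z against a no-target control; an optional
  multiplicative normalisation factor is exposed (default 1.0) for
  depth-scaled variants;
- MLE enrichment ratio = ((c_t+½)/N_t)/((c_c+½)/N_c); conditioning on
  c_t+c_c makes c_t binomial with odds ∝ the rate ratio, so a
  Clopper–Pearson interval for that proportion transforms monotonically
  into a CI for the ratio. A 10⁵-draw parametric bootstrap in the tests
  confirms ≥ nominal−2% coverage.

Synthon aggregation groups on the fixed cycles' `bb_i` columns and sums
counts over the free cycles (mono = 1 fixed, di = 2 fixed for 3 cycles);
conservation of totals is asserted. Replicate overlap reports, for each
subset of replicates, the keys passing a user-chosen threshold in exactly
that subset. No multiple-testing correction is applied by default —
thresholds are the user's. The ML baseline undersamples the majority
class to balance (2×min class size), then runs seeded stratified k-fold
(default 5) of a pluggable fit/predict classifier (default random forest,
100 trees) against a majority-class dummy; a classifier that cannot beat
the dummy indicates no learnable signal at that representation.

## Simulator

Reads = 0–10 random flank bases + schema-rendered barcode (constants
verbatim, sampled compound's tags, uniform random UMI) + 0–10 flank
bases, with i.i.d. substitutions (uniform among the three other bases)
and single-base indels (insert/delete 50:50), ~half the reads
reverse-complemented. Compounds are drawn from an explicit weight vector;
`planted_enrichment_weights` raises a seeded hit fraction to fold× the
background weight and renormalises, giving an expected hit read share of
f·h/(f·h+1−h). Everything derives from one seed; FASTQ(.gz) output is
byte-identical across runs (gzip mtime pinned).

This error model is intentionally not sequencer-realistic: no
homopolymer-length errors, quality correlation, chimeras or PCR bias.
Passing tests therefore demonstrate the correctness of the codes,
alignment, counting and statistics under a controlled error budget — not
decode rates on any particular instrument.

## Problem sizes and defaults

The benchmark selection is one synthetic 3-cycle library, 24 blocks per
cycle (13,824 compounds), 8-bp distance-3 tags, 10-bp UMI, 50,000 reads
at 0.5% substitution + 0.1% indel rate, tolerances 0.1/0.1 — a desk-scale
stand-in for a small academic DEL screen. Unit and property tests use
smaller libraries (8–12 blocks/cycle, a few thousand reads) chosen so the
full suite stays fast while still covering every code path; exhaustive
code checks run at n=7 (256 × 21 single errors) and n=8 parity
(256 × 252 double errors), where exhaustion is feasible. Full-codebook
distance checks use the linear-code identity (min distance = min nonzero
codeword weight) above 4,096 codewords and direct pairwise comparison
below, plus a direct pairwise certificate on 500-codeword samples at
every length.

## Known limitations

- Linear reaction schemes only; no stereochemistry enumeration.
- Decoding ignores base qualities and does not attempt sample-index
  demultiplexing or basecalling.
- Tag calling refuses length-changed (indel-bearing) tag spans rather
  than attempting indel-tolerant tag decoding.
- The `cluster1` UMI mode is a greedy heuristic, not a network-based
  deduplicator.
- No GC-content/repeat filtering of generated barcodes (by design, for
  now).
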