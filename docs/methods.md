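# Methods

This note records the model and conventions behind `readprobe`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## The reverse-mapping model

The object being indexed is the sample, not the reference: all reads are
concatenated into a single text with a sentinel separator, and an
FM-index (suffix array → BWT → rank structure → sampled suffix array)
over that text answers exact substring count and locate queries in time
proportional to the pattern length. Queries are decomposed into k-mers,
every k-mer hit is mapped back to the read containing it, and each query
reports the number of *distinct* reads (or read pairs) it touched.
Matching is exact; sensitivity in the presence of sequencing errors
comes entirely from the k/s trade-off (shorter k-mers and denser steps
give more chances that some window of a read is error-free).

## Index conventions

* **Suffix order.** Suffixes are ordered as the rotations of the text,
  with ties broken by text position, and the final text terminator is
  encoded internally as a symbol strictly smaller than the read
  separators (`terminator < $ < A < C < G < N < T`). The distinct
  terminator makes every rotation unique, so the LF mapping is exact at
  *every* BWT row; locate walks may cross read boundaries without
  special cases, and BWT inversion is a clean identity (asserted in
  tests). Externally both separator codes render as `$`, and counts and
  positions are exactly those of the conventional multi-string suffix
  array with position-ranked sentinels.
* **Construction.** The suffix array is built by prefix doubling over
  numpy `lexsort` (O(n log² n), exiting as soon as ranks are distinct —
  a handful of rounds for read-like texts). A sorted-rotations oracle in
  the test suite cross-checks it on random inputs. At the scales this
  package targets (millions of text bases) construction takes seconds.
* **Rank structure.** The occurrence table is stored dense:
  `occ[p, c] = |{i < p : BWT[i] = c}|`, i.e. O(1) rank at ~28 bytes per
  text base. This is a deliberate memory-for-speed trade that also makes
  backward search fully vectorizable across a batch of same-length
  k-mers (one numpy gather per pattern position for the whole batch).
  The rank structure is a contract — a succinct wavelet-tree encoding
  would change the constant factors, not any result.
* **Sampled suffix array.** Rows whose suffix position is ≡ 0 (mod
  `sample_rate`, default 16) keep their position; locate LF-walks at
  most `sample_rate − 1` steps, vectorized over all pending hits at
  once. Counts and positions are invariant in `sample_rate` (tested at
  1, 4, 32). Default 16 balances memory against locate cost.
* **N bases** are kept in the text as a fifth symbol and match only
  exactly. **Case** is folded to upper, `U → T`.
* **Serialization** is a versioned binary file (magic, version, JSON
  header with the store manifest, BWT payload, sampled-SA slots/values).
  Rank tables are rebuilt on load; saves are byte-deterministic;
  truncated or wrong-version files fail closed.

## Read bookkeeping

Paired mates are interleaved (R1_i at ordinal 2i, R2_i at 2i+1) so
`pair_id = ordinal // 2`; nothing downstream depends on this choice
beyond that one map. Chunk splitting partitions reads contiguously by
ordinal, never separating mates, and each chunk carries its global
ordinal offset. Reverse-complement handling has two equivalent routes,
asserted equivalent in tests: the default searches each k-mer and its
reverse complement against a forward-only index; alternatively the index
can include an RC copy of each read, which shares the primary read's
ordinal for counting.

## Search semantics where the field's conventions diverge

* **Centered generation** starts at `max(0, c−k+1)` (c = ⌊L/2⌋) and
  steps by `s` up to `min(c, L−k)`, always emitting the rightmost
  feasible start, so both extreme windows covering the center exist.
  **Sliding generation** steps from 0 and always emits the final window
  at `L−k`; otherwise 3′-end bases would be systematically unsearchable.
* **max_occ is global**: a k-mer's occurrences are summed across chunks
  before the threshold is applied. This is what keeps chunked and
  monolithic searches bit-identical; per-chunk locate calls that exceed
  the ceiling return an overflow marker carrying the exact total so the
  global rule can still be evaluated.
* **unique_reads drops contested reads from all queries** (no winner).
  The alternative — assigning to one winner — would need an arbitrary
  order; dropping is order-independent and deterministic.
* **Non-unique k-mers** are identified after reverse-complement
  expansion: a k-mer equal to (or the RC of) another query's k-mer is
  removed, and every affected query carries a `flag_nonunique_kmer`. A
  palindromic k-mer within one query maps once.
* **Thread invariance.** The k-mer list is partitioned across workers
  and results are keyed by (k-mer, chunk), so the merged result is
  identical for any thread count — threads change wall time only.

Defaults: genotyping `k=31, s=10`, centered, `max_occ=200`, unique
k-mers required; pathogen screening `k=30, s=5`, sliding, unique reads +
unique k-mers, `max_occ=2000`. Query flank defaults to 50 (101 bp
queries), which comfortably exceeds both default k values.

## Genotyping rule

The printed rule triple uses strict inequalities and leaves equality
with the threshold and the double-failure case undefined. We totalize
it with the least surprising reading: *supported* means
`count ≥ minCount`; both supported → 0/1, only REF → 0/0, only ALT →
1/1, neither → `./.` (no-call). `minCount` defaults to 3 and is surfaced
in the CLI and the VCF header. Offending-k-mer flags propagate into the
VCF INFO field (`NONUNIQ_KMER`, `OVERMAX_KMER`).

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the method's claims
rest on: uniform random genomes; biallelic SNPs planted on two
haplotypes with genotypes drawn (default ¼, ½, ¼ for 0/0, 0/1, 1/1) on
a jittered grid that guarantees a minimum spacing (so SNP queries never
overlap) and an optional edge margin (so every site admits a full
centered query window); uniform-coverage stranded reads with i.i.d.
substitution errors; and pathogen reads spiked into a background at
exact counts. It deliberately omits indels (under exact matching an
indel read behaves like a heavily substituted read), realistic error
profiles, GC/coverage bias, and duplicates. Passing benchmarks therefore
demonstrate the correctness of the counting machinery and the k/s error
trade-off — not robustness to real-instrument artifacts, repetitive
genomes, or contamination, where the offending-k-mer flags and upstream
read filtering matter.

Every simulation is reproducible from an integer seed, and truth
(planted genotypes, per-read origins, spiked read names) is returned
with the data.

## Benchmark problem sizes

Chosen to exercise each mechanism at desk scale: the FM-index oracle
uses 100 random stores of 20–200 reads × 100 bp against a naive per-read
window scan (every k-mer, k ∈ {11, 21, 31}); read recovery uses four
5–20 kb pathogen genomes at 100× error-free coverage (the test suite
uses the 5–8 kb end of that range, the acceptance script 5–20 kb);
spike-ins use a 50 kb background at 10,000 reads with pathogens spiked
at {0, 50, 500, 5000} reads, error-free and at 1% substitution error;
genotyping uses 200 SNPs on a 40 kb genome at 30× diploid coverage. For
the noisy spike-in, the analytic detection bound uses the three disjoint
on-grid 30-mer windows guaranteed inside any 100 bp read:
`P(detect) ≥ 1 − (1 − 0.99³⁰)³ ≈ 0.982`, and observed recovery
(~99.5%) sits above it, as expected since the ~15 overlapping windows
give more chances than the disjoint bound credits.

## Known limitations

Exact matching only — no mismatch-tolerant search or minimizer
approximation; sensitivity under error is purely a k/s choice. The
dense rank table is memory-hungry for very large read sets (a succinct
encoding is the natural extension). Genotyping assumes biallelic SNPs
with centered, non-overlapping queries; indels and multi-allelic sites
are skipped at query generation. Only VCF output is implemented for
genotype calls.
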