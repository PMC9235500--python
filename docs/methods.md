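# Methods

## Model and assumptions

`poresieve` decides, from a short error-prone prefix of a nanopore read,
whether the read is contained in an indexed reference. Containment is
k-mer counting against per-fragment Bloom filters; acceptance is a
confidence bound on how many k-mers an error process is expected to
destroy. The two pieces make different assumptions, listed with each.

### Interleaved Bloom filter

The reference is fragmented (default 100 kb fragments, 500 nt overlap)
because at k = 13 the k-mer space (4¹³ ≈ 6.7×10⁷) is far smaller than a
large genome's k-mer count: one genome-wide filter would saturate and lose
specificity, whereas a 100 kb fragment holds at most 99 988 k-mers.
Fragments never span records; within a record, fragment starts advance by
`fragment_size − overlap` and the last fragment is clipped at the record
end (a tail shorter than k, possible only when overlap < k − 1, is merged
into the previous fragment). With the default overlap ≥ k − 1, every k-mer
of the record occurs intact in at least one fragment.

Per-bin filter size follows the closed-form inversion of the Bloom FP
formula at capacity `max_kmer = F − k + 1`; it is evaluated with
`log1p`/`expm1` so the integer bit count is exact even when the per-bit
probability is ~10⁻⁷. The FP target is per bin; querying many bins
inflates the chance that *some* bin shows a spurious single-k-mer hit, but
classification never rests on single hits — the match threshold (tens of
k-mers) absorbs this.

Bit layout: subvector-major, bins padded to a multiple of 64, bit address
= subvector_index × bin_count_padded + bin_index, packed little-endian
into 64-bit words — so the h-way AND and the per-bin popcount are
word-wise operations, and index files are bit-exact across platforms.
Hashing is a splitmix64 finalizer applied to the 2-bit-packed k-mer XOR a
seed, reduced mod `Bits_SBF`; the h seeds are fixed published constants
derived from the splitmix64 stream and are stored in the index header.
Chi-square tests in the suite check the uniformity of this family.

K-mers are *canonical* (lexicographic minimum of the k-mer and its reverse
complement) on both insert and query, so matching is strand-agnostic
without doubling the index. Windows containing non-ACGT symbols are
skipped on both sides, and the number of valid windows (`L_queried`) is
what the threshold is computed from.

### Match threshold

Under i.i.d. per-base substitution at rate e, a k-mer is erroneous with
probability q = 1 − (1−e)^k. For L k-mers, E[N_err] = Lq, and the variance
uses the closed form that accounts for the covariance of overlapping
k-mers:

    Var(N_err) = L(1−q)(q(2k + 2/e − 1) − 2k) + k(k−1)(1−q)²
               + (2(1−q)/e²)((1 + (k−1)(1−q))e − q).

At k = 1 this reduces to the binomial variance Le(1−e); at e = 0 the
variance is defined as 0 (analytic limit), and tiny negative results from
cancellation are clamped to 0. A 10⁵-trial Monte Carlo of the error
process (in the acceptance suite) agrees with the mean within 0.5 k-mers
and the variance within 5% at L = 348, k = 13, e = 0.1.

The acceptance threshold is min[N_match] = ⌊L − (E[N_err] + z_α√Var)⌋
clamped to [1, L]; flooring is conservative in the accept direction, and
the clamp at 1 prevents a degenerate threshold ≤ 0 that would accept
everything. z_α = Φ⁻¹(1 − α/2) (α = 0.05 → 1.959964). The model is
substitution-only; indels in real or simulated reads effectively act as
additional substitutions at the k-mer level and are absorbed by the
confidence margin — the depletion-screen test passes with a mixed
substitution/indel channel at ~10% total error.

The threshold is recomputed from the *actual* number of valid k-mers
queried (`L_queried`), not the nominal read length, so ambiguous bases do
not silently relax the bound. When a read is re-classified after more
chunks arrive, the full accumulated sequence is used and the threshold is
recomputed at the new length.

### Decision loop

Parameters (units, defaults, why):

| parameter | default | meaning |
|---|---|---|
| k | 13 nt | k-mer length; small enough to tolerate ~10% error |
| h | 3 | hash functions per filter |
| p | 0.01 | per-bin FP target |
| fragment_size | 100 000 nt | bin granularity vs. k-mer-space saturation |
| overlap | 500 nt | ≥ k−1 keeps junction k-mers; builder warns below that |
| e | 0.10 | expected per-base error of the basecaller |
| α | 0.05 | 1 − confidence of the threshold |
| min length | 200 nt | below this no classification is attempted |
| max length | 1500 nt | give-up point for undecided reads |
| chunk | 180 nt | 0.4 s of sequencing at 450 nt/s |
| ejection latency | 1 chunk | nt sequenced after an unblock before the molecule exits |

Matching a depletion index ⇒ `unblock`; matching a target index ⇒
`stop_receiving`. When both roles match, the target wins — with both
filter roles loaded, protecting enrichment targets is the safer error.
An undecided read at the 1500 nt cap continues as a normal read
(`stop_receiving`), except in target-only mode where anything that never
matched a target is unblocked; these two behaviours mirror the two
experiment designs (depletion-only vs. targeted enrichment). A decided
read never re-decides; a late chunk for it is ignored with a warning,
matching sequencer race semantics.

## The simulator

The stream simulator emulates: random uniform (GC-parameterized)
reference genomes; reads drawn from either strand with log-normal lengths
(configurable median, truncated at the record length — a typical shape
for nanopore libraries); an i.i.d. substitution/insertion/deletion channel
(defaults 6%/2%/2%, ~90% mean identity, a plausible split for
CPU-basecalled data); fixed-size chunk emission; and *real-run* unblock
semantics — an ejected molecule stops at decision length + latency. It
does **not** emulate: signal space or basecaller error structure
(homopolymer compression, quality correlation along the read), genuine
genome composition (repeats, shared k-mers between related taxa), pore
blocking/occupancy, or playback-mode read splitting. Passing tests
therefore demonstrate the statistical contract of the method under its own
error model, not performance on real communities, where inter-genome
k-mer sharing would raise false matches between related references.

Time is logical: chunk cadence is an accounting device, and no wall-clock
throughput claims are made or tested.

## Numerical and design choices

- Sizing/FP formulas in log domain (`expm1`, `log1p`) — exact integer bit
  counts, stable FP values for multi-megabit filters.
- Ties in the best-bin argmax break toward the lowest bin index
  (deterministic classification traces).
- Degenerate inputs: fragments or reads shorter than k are build-time /
  call-time errors; an empty valid-k-mer set classifies as no-match rather
  than raising.
- Index serialization is a fixed little-endian layout (magic, version,
  parameters incl. seeds, fragment table, bit matrix); round trips are
  bit-exact and malformed files raise distinct, descriptive errors.
- Builds are deterministic: identical inputs and parameters give
  byte-identical index files.
- The pure-Python/numpy bit matrix favours clarity and vectorized batch
  queries; single-read latency is not optimized (no SIMD popcount or
  threading), which is acceptable for the simulator-hosted loop.

## Problem sizes in the test and acceptance runs

Synthetic references are 100 kb–1 Mb (vs. gigabase genomes in real use),
read sets 200–5000, Monte-Carlo trials 10⁵, FP probes 1.5×10⁵. These sizes
keep every statistic's sampling error well inside the asserted tolerances
while the whole suite runs in well under a minute; the method's costs grow
linearly in reference size, so nothing qualitative changes at scale except
classification speed.

## Known limitations

- The threshold model ignores indels and correlated basecaller errors;
  the confidence margin absorbs moderate deviations but the nominal
  1 − α recall guarantee is exact only for the substitution channel.
- Random synthetic genomes are nearly k-mer-disjoint; specificity numbers
  on them are an upper bound on what related real genomes would give.
- One index per filter role; no taxonomic labelling of bins, no
  compressed or hierarchical filter layouts, no dynamic deletion.
- The ejection latency is a modeling parameter (default one chunk), not a
  measured hardware constant.
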