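# Methods

## Problem and model

Given a set of reads `R` and a query sequence `s`, a read `r` is *similar*
to `s` when they share at least `t` canonical k-mers:
`|k-spectrum(r) ∩ k-spectrum(s)| ≥ t`. readtint answers this by indexing,
for every solid m-minimizer `y`, the color
`{r ∈ R : y ∈ {μ(x) : x ∈ k-spectrum(r)}}`. Since every k-mer of a read
contributes its minimizer to the read's minimizer set, the per-k-mer map
`{r : x ∈ k-spectrum(r)}` is contained in `{r : μ(x) ∈ minimizers(r)}`:
minimizer-level retrieval can only over-report. The verification stage
restores exactness over the candidates by recounting shared canonical
k-mers.

Retrieval therefore has one structural caveat: reads reachable *only*
through filtered-out minimizers (abundance below `min_abundance` or above
`max_abundance`) can be missed. With filtering disabled the superset
guarantee is unconditional, which is what the no-false-negative tests
assert.

## Minimizer scheme

- Canonical k-mers and m-mers use A<C<G<T on 2-bit packed integers, so
  numeric comparison equals lexicographic comparison. `k ≤ 31` keeps a
  canonical k-mer in one `uint64`.
- The minimizer order is a seeded splitmix64 finalizer on the packed
  canonical m-mer ("random minimizers"); the seed lives in `IndexParams`
  and in the index header, so an index is fully reproducible. A pure
  lexicographic order is exposed (`order="lex"`) purely as a test hook.
- Each m-mer is canonicalized *before* ordering. This makes the minimizer
  set of a sequence strand-symmetric window by window, so a k-mer and its
  reverse complement always select the same minimizer regardless of which
  strand's form is canonical.
- Ties are broken by leftmost window position. Two *distinct* m-mers with
  equal hash are not further disambiguated (a 2^-64 event per pair);
  equal m-mers compare equal anyway.
- Any window containing a non-ACGT symbol contributes no k-mer (standard
  practice for ambiguity codes).
- On i.i.d. sequence the scheme selects about `2/(k-m+1)` of positions —
  the expected density of random minimizers, about twice the theoretical
  floor `1/(k-m+1)`; a property test pins the density to `[1, 3]` times
  the floor.

## Abundance filtering

Counting is at the minimizer level (an order of magnitude fewer keys than
k-mers) and *per read*: a read contributes each of its distinct minimizers
once, so abundance equals the number of reads containing the minimizer and
tracks coverage directly. "Appearing T times" is thereby pinned to
read-level occurrence; per-occurrence counting would inflate counts inside
repetitive reads without changing which reads a color contains.

The `CountingFilter` is a single-row count-min sketch: one seeded hash,
2^`filter_log2_size` saturating 16-bit counters capped at
`max_abundance+1`. One row keeps the never-undercount guarantee trivially;
collisions only inflate counts, which at the lower abundance bound can
only *admit* extra minimizers (recall-safe) and at the upper bound can
*evict* genuine ones — both directions are measured, not assumed away, by
the evaluation module. The default size is 2^26 (the desk-scale variant);
2^32 is available by parameter. An `ExactCounter` provides the
collision-free oracle and the `counting="exact"` build mode; with no
collisions the two select identical solid sets.

The build makes one decomposition pass (per-read distinct minimizer sets
are kept in memory), feeds counting, then applies both abundance bounds at
lookup before color insertion. The upper bound is thus a lookup-time
exclusion, matching the memory-driven rationale for dropping over-abundant
keys while still counting them.

## Colors and encoding

Read-id lists are interned content-addressed (byte-wise equality of the
packed `uint32` array) so each distinct color is stored once; minimizers
reference colors by id. On disk each color is delta-encoded (first id
absolute, then gaps) with LEB128 varints. At coverage-like densities the
gaps are small and fit one byte, giving the ≥3× reduction the acceptance
check asserts. No general-purpose compressor is layered on top: the codec
contract is lossless round-trip and the size bound, not bit-compatibility
with any particular SIMD codec. The index file is a little-endian binary
with magic `TDBG`, a version byte and the full `IndexParams` (including
the hash seed) in the header; serialization is byte-deterministic for
identical input and parameters.

## Queries

The candidate stage counts *distinct* shared indexed minimizers per read
(multiplicity ignored — cheaper, and sufficient for the superset guarantee
at the minimizer level). Thresholds are absolute (≥1) or a ratio in
(0, 1]; a ratio is taken relative to the query's distinct minimizers
present in the index, default 0.3. Ratio-over-indexed-minimizers (rather
than over k-mers) was chosen so the threshold adapts to what the index can
actually see for this query; the evaluation module uses the matching ratio
over the query's distinct k-mers for the truth side. Verification
recounts `|k-spectrum(read) ∩ k-spectrum(query)|` with numpy set
intersections, fetching read sequences from memory, from a dict, or from
the source FASTA/FASTQ (seeking by the record offsets stored in the index
for uncompressed files).

## Synthetic data

The generator emulates whole-genome long-read sequencing: an i.i.d.
uniform linear genome (bacterial genomes are circular; linearity only
perturbs edge coverage and none of the measured quantities depend on it);
reads with uniform start positions, normal lengths (default 10 kb ± 1 kb,
floored at 200 bp, truncated at the genome end) drawn from both strands
until total bases reach `coverage × genome_length`; independent per-base
errors with an 80/10/10 substitution/insertion/deletion mix (a
substitution-heavy long-read-like regime; platforms differ mainly in the
indel share, which is configurable). Positive queries are error-free
genome substrings of 500–10 000 bp; negative queries are i.i.d. random
sequences of matched lengths. All stages draw from salted substreams of
one seed and are fully deterministic.

What this does *not* model: repeat structure (an i.i.d. genome has
essentially no repeated 31-mers, so the upper abundance bound is exercised
only synthetically), platform-specific error profiles (homopolymer
artifacts), chimeras, and coverage biases. Passing tests therefore
demonstrate the structural guarantees and the error-rate regime of the
method, not its behavior on repeat-rich genomes.

## Evaluation conventions

Truth is the exact k-mer-to-reads mapping (`OracleIndex`) with no
minimizers and no filtering. Rates are **pair-level micro-averages** over
a query batch: FPR = reported pairs absent from truth / reported pairs;
TPR = truth pairs reported / truth pairs. Pair-level was chosen because a
per-query definition would hide volume effects of large candidate lists;
per-query macro averages are also computed for transparency, and the
definition is printed in the metrics output header. A reported pair
counts as a false positive whenever the read fails the shared-k-mer
criterion, even if it passed the minimizer criterion honestly. Zero
denominators yield NaN with a warning.

The quantitative measurements run the full pipeline at a 500 kb / 50X /
1000-query scale in `scripts/acceptance.py` and a 150 kb / 40X / 150-query
scale in the test suite; the structural no-false-negative checks use
twenty simulations spanning 100 kb–1 Mb genomes, 10–50X coverage and 0–3%
error rates with a handful of queries each. These sizes keep the whole
suite in single-digit minutes on one CPU while leaving thousands of
(query, read) pairs per measurement.

## Numerical and degenerate-input choices

- Sequences shorter than `k` yield empty spectra/results, not errors;
  empty read sets are an error.
- `resolve_threshold` floors ratio thresholds at 1; a query with no
  indexed minimizer gets threshold 1 and no hits.
- The oracle refuses instances beyond ~4×10^8 (k-mer, read) pairs to stay
  desk-scale in memory.
- Counting-filter batches are per-read distinct sets; saturation is
  re-applied after each batch (a slot can transiently exceed the cap by
  the batch multiplicity, far below the uint16 range).

## Known limitations

- `k ≤ 31` (single-word packing). `m` is unrestricted up to `k`.
- The index keeps decoded colors in memory; no partial/streaming load.
- No index merging or dynamic updates; rebuild to add reads.
- Minimizer-level filtering is coarser than k-mer-level filtering:
  erroneous k-mers sharing a minimizer with solid k-mers survive it, which
  is precisely the false-positive source the verification stage removes.
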