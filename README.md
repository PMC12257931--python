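# readtint

**readtint** indexes a long-read sequencing dataset so that, given any query
sequence, it returns the *reads* containing k-mers of that query — the
k-mer-to-reads problem. It is aimed at de novo workflows (genotyping,
error correction, assembly polishing, dataset mining) that need read-level
resolution without a reference genome or an assembly.

## The structure

Treating every read as its own "color" in a colored de Bruijn graph — a
*tinted* de Bruijn graph — is exact but prohibitively large: each of the
billions of k-mers would carry a list of read identifiers. readtint stores
the lossy minimizer-level variant instead:

- Every k-mer `x` (canonical: the lexicographic min of `x` and its reverse
  complement) is represented by its **m-minimizer** `μ(x)`, the smallest
  m-mer of `x` under a seeded pseudo-random order. Overlapping k-mers
  usually share a minimizer, so there are far fewer keys than k-mers.
- Each minimizer maps to its **color**: the sorted list of ids of the reads
  containing a k-mer with that minimizer. Overlapping reads make most
  colors identical, so distinct colors are interned once in a color table
  and referenced by id; on disk the lists are delta-encoded and
  varint-packed (≳3× smaller than raw 32-bit ids at sequencing-like
  coverage).
- Sequencing errors produce rare keys. A single-row counting filter tracks
  the read-level abundance of every minimizer, and only **solid** minimizers
  (abundance within `[min_abundance, max_abundance]`, default `[2, 5000]`)
  are indexed. The filter can over-count but never under-counts, so a
  sufficiently abundant k-mer's minimizer is never discarded.

Because `x ∈ read r` implies `μ(x) ∈ minimizers(r)`, a read sharing `t`
k-mers with a query shares its indexed minimizers too: retrieval by shared
minimizer count **over-reports but never misses** (false positives, no false
negatives, relative to the indexed keys). An optional verification stage
recounts exact shared canonical k-mers `|k-spectrum(r) ∩ k-spectrum(s)|`
per candidate and removes collision false positives, leaving exactly the
reads meeting the similarity criterion `|k-spectrum(r) ∩ k-spectrum(s)| ≥ t`.

Defaults are `k=31`, `m=15`, abundance `[2, 5000]`, a 2^26-slot counting
filter, and a ratio threshold of 0.3 of the query's indexed minimizers.

## Worked example

```sh
readtint simulate --genome-length 100000 --coverage 20 --read-length 5000 \
    --error-rate 0.01 --seed 42 --n-pos 3 --n-neg 1 --outdir demo
readtint index demo/reads.fa demo/reads.idx --counting exact --min-abundance 2
# indexed 411 reads: 12911 solid minimizers, 10979 distinct colors -> demo/reads.idx
readtint query demo/reads.idx demo/queries.fa --threshold 0.3 \
    --verify --reads demo/reads.fa --out demo/hits.tsv
```

`demo/hits.tsv` holds one row per (query, read) pair:

```
# k=31 m=15 abundance=[2,5000] threshold=0.3 verified=True
query_id  read_id  shared_minimizers  shared_kmers
q0        68       441                3458
q0        81       313                2487
q0        90       483                3838
...
```

Query `q0` is a genome substring; read 68 shares 441 distinct indexed
minimizers with it (which made it a candidate at the 0.3 ratio threshold)
and, after verification, exactly 3458 canonical 31-mers. The negative
query `q3` (random sequence) reports no reads. The same pipeline can be
scored against the exact brute-force k-mer oracle:

```sh
readtint evaluate demo/reads.fa demo/queries.fa --counting exact \
    --threshold 0.3 --error-rate 0.01 --out demo/metrics.tsv
# fpr=0.1149 tpr=1.0000 -> demo/metrics.tsv
```

All reads meeting the exact shared-k-mer criterion were retrieved
(`tpr=1.0`); unverified candidate lists carry a small false-positive
fraction that `--verify` removes.

The same API is available in Python (`readtint.build_index`,
`readtint.query_candidates`, `readtint.verify_hits`,
`readtint.OracleIndex`, ...).

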