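"""k-mer-to-reads queries over a minimizer-tinted index.

Retrieval is two-stage. The candidate stage accumulates, for every distinct
query minimizer present in the index, the reads of its color, and reports
reads sharing at least ``t`` distinct indexed minimizers with the query.
Since a shared k-mer implies a shared minimizer, every read sharing at least
``t`` indexed minimizers is reported — the structure over-reports but never
misses at the minimizer level. The optional verification stage recounts the
exact number of shared canonical k-mers between the query and each candidate
read, and drops candidates below a k-mer threshold, removing
minimizer-collision false positives.

Thresholds are either absolute integers (>= 1) or ratios in (0, 1]; a ratio
is taken relative to the query's distinct minimizers present in the index
(candidate stage) or to the query's distinct canonical k-mers (verification).
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .index_builder import KmerReadIndex, fetch_read, read_sequences
from .kmer_minimizer import sequence_kmers, sequence_minimizers

U64 = np.uint64


def resolve_threshold(threshold: Union[int, float], n: int) -> int:
    """Convert a threshold to an absolute count (>= 1) given base size *n*."""
    if isinstance(threshold, (bool, np.bool_)):
        raise ValueError("threshold must be an integer >= 1 or a ratio in (0, 1]")
    if isinstance(threshold, (int, np.integer)):
        if threshold < 1:
            raise ValueError("absolute threshold must be >= 1")
        return int(threshold)
    if isinstance(threshold, float):
        if not (0.0 < threshold <= 1.0):
            raise ValueError("ratio threshold must lie in (0, 1]")
        return max(1, math.ceil(threshold * n))
    raise ValueError(f"invalid threshold {threshold!r}")


@dataclass
class QueryResult:
    """Hits of one query, sorted by read id.

    ``shared_minimizers[i]`` is the number of distinct indexed minimizers
    shared with ``read_ids[i]``; ``shared_kmers`` is filled by the
    verification stage (None while unverified). ``query_kmers`` carries the
    query's sorted distinct canonical k-mers so verification needs no access
    to the query sequence.
    """

    query_id: str
    read_ids: np.ndarray
    shared_minimizers: np.ndarray
    shared_kmers: Optional[np.ndarray]
    n_query_kmers: int
    n_query_solid_minimizers: int
    threshold: int
    query_kmers: np.ndarray

    @property
    def verified(self) -> bool:
        return self.shared_kmers is not None

    def __len__(self) -> int:
        return int(self.read_ids.size)


def query_candidates(
    index: KmerReadIndex,
    seq: str,
    threshold: Union[int, float],
    query_id: str = "query",
) -> QueryResult:
    """Candidate reads sharing enough distinct indexed minimizers with *seq*.

    Guarantee: every read sharing >= t distinct indexed minimizers with the
    query is reported. A query shorter than k yields an empty result.
    """
    params = index.params
    qmins = sequence_minimizers(seq, params, distinct=True)
    found, cids = index.lookup(qmins)
    n_found = int(found.sum())
    t_abs = resolve_threshold(threshold, n_found)
    qkmers = sequence_kmers(seq, params.k)

    if n_found == 0:
        empty = np.empty(0, dtype=np.int64)
        return QueryResult(
            query_id, empty, empty.copy(), None, int(qkmers.size), 0, t_abs, qkmers
        )

    # Each distinct minimizer contributes +1 to every read of its color;
    # several minimizers may share one color id, hence the weight.
    ucids, weights = np.unique(cids, return_counts=True)
    ids = np.concatenate([index.color(int(c)) for c in ucids])
    wts = np.repeat(weights, [index.color(int(c)).size for c in ucids])
    counts = np.bincount(ids, weights=wts, minlength=index.n_reads).astype(np.int64)
    hit = counts >= t_abs
    read_ids = np.flatnonzero(hit).astype(np.int64)
    return QueryResult(
        query_id=query_id,
        read_ids=read_ids,
        shared_minimizers=counts[hit],
        shared_kmers=None,
        n_query_kmers=int(qkmers.size),
        n_query_solid_minimizers=n_found,
        threshold=t_abs,
        query_kmers=qkmers,
    )


class ReadStore:
    """Read-sequence provider for the verification stage.

    Accepts an in-memory list/dict of sequences, or a FASTA/FASTQ path
    (seekable by record offset when the index recorded offsets, otherwise
    parsed once into memory on first access).
    """

    def __init__(
        self,
        source: Union[Sequence[str], Mapping[int, str], str, Path],
        offsets: Optional[np.ndarray] = None,
    ):
        self._cache: Optional[dict[int, str]] = None
        self._offsets = offsets
        self._path: Optional[Path] = None
        if isinstance(source, (str, Path)):
            self._path = Path(source)
            if not self._path.exists():
                raise FileNotFoundError(f"read source file not found: {self._path}")
        elif isinstance(source, Mapping):
            self._cache = dict(source)
        else:
            self._cache = dict(enumerate(source))

    def get(self, read_id: int) -> str:
        if self._cache is not None and read_id in self._cache:
            return self._cache[read_id]
        assert self._path is not None
        if self._offsets is not None and self._path.suffix != ".gz":
            return fetch_read(self._path, int(self._offsets[read_id]))
        self._cache = {
            rec.read_id: rec.sequence
            for rec in read_sequences(self._path, record_offsets=False)
        }
        return self._cache[read_id]


def verify_hits(
    index: KmerReadIndex,
    reads: Union[Sequence[str], Mapping[int, str], str, Path, ReadStore],
    result: QueryResult,
    t_kmers: Union[int, float],
) -> QueryResult:
    """Exact shared-k-mer recount over the candidate reads.

    For each candidate, computes |k-spectrum(read) ∩ k-spectrum(query)| over
    canonical k-mers, attaches it, and drops reads below ``t_kmers`` (ratio
    thresholds are relative to the query's distinct k-mers). The output is
    exactly the candidate reads satisfying the shared-k-mer similarity
    criterion.
    """
    store = reads if isinstance(reads, ReadStore) else ReadStore(
        reads, offsets=index.read_offsets
    )
    t_abs = resolve_threshold(t_kmers, result.n_query_kmers)
    qk = result.query_kmers
    shared = np.empty(result.read_ids.size, dtype=np.int64)
    for i, rid in enumerate(result.read_ids.tolist()):
        rk = sequence_kmers(store.get(rid), index.params.k)
        shared[i] = np.intersect1d(qk, rk, assume_unique=True).size
    keep = shared >= t_abs
    return replace(
        result,
        read_ids=result.read_ids[keep],
        shared_minimizers=result.shared_minimizers[keep],
        shared_kmers=shared[keep],
    )


def write_results_tsv(
    results: Sequence[QueryResult],
    out=sys.stdout,
    params_line: Optional[str] = None,
) -> None:
    """TSV output: one row per (query, hit); header states run parameters."""
    close = False
    if isinstance(out, (str, Path)):
        out = open(out, "w")
        close = True
    try:
        if params_line:
            out.write(f"# {params_line}\n")
        out.write("query_id\tread_id\tshared_minimizers\tshared_kmers\n")
        for res in results:
            sk = res.shared_kmers
            for i, rid in enumerate(res.read_ids.tolist()):
                kcol = "" if sk is None else str(int(sk[i]))
                out.write(
                    f"{res.query_id}\t{rid}\t{int(res.shared_minimizers[i])}\t{kcol}\n"
                )
    finally:
        if close:
            out.close()
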