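"""Brute-force oracle and false-/true-positive rate measurement.

The :class:`OracleIndex` is the exact k-mer-to-reads mapping (every canonical
k-mer of every read, no minimizers, no filtering). It defines ground truth
for retrieval: a read is *similar* to a query when they share at least ``t``
canonical k-mers. Rates are micro-averaged over all (query, read) pairs of a
batch — FPR is the fraction of reported pairs absent from the truth, TPR the
fraction of truth pairs reported; per-query macro averages are also computed
since the pair-level convention is a choice of this package.

``retrieval_experiment`` and ``no_false_negative_experiment`` wire the whole
pipeline (simulate -> build -> query -> score) and are shared by the test
suite, the acceptance script and the CLI.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .index_builder import KmerReadIndex, build_index, delta_encode
from .kmer_minimizer import IndexParams, sequence_kmers
from .query_engine import query_candidates, resolve_threshold, verify_hits
from .synthetic_data import SimulationConfig, make_queries, simulate_genome, simulate_reads

U64 = np.uint64

# In-memory oracle guard: (k-mer, read) pairs, ~12 bytes each.
_MAX_ORACLE_PAIRS = 400_000_000


class OracleIndex:
    """Exact canonical-k-mer -> sorted read-id mapping over a read set."""

    def __init__(self, kmers: np.ndarray, read_ids: np.ndarray, n_reads: int, k: int):
        self._kmers = kmers  # sorted, parallel to read_ids
        self._reads = read_ids
        self.n_reads = n_reads
        self.k = k

    @classmethod
    def from_reads(cls, sequences: Sequence[str], k: int) -> "OracleIndex":
        """Build from read sequences; guarded to desk-scale instances."""
        kchunks: list[np.ndarray] = []
        rchunks: list[np.ndarray] = []
        total = 0
        for rid, seq in enumerate(sequences):
            uk = sequence_kmers(seq, k)  # distinct per read => unique pairs
            total += uk.size
            if total > _MAX_ORACLE_PAIRS:
                raise ValueError(
                    "oracle too large for in-memory construction "
                    f"(> {_MAX_ORACLE_PAIRS} k-mer/read pairs)"
                )
            kchunks.append(uk)
            rchunks.append(np.full(uk.size, rid, dtype=np.uint32))
        allk = np.concatenate(kchunks) if kchunks else np.empty(0, dtype=U64)
        allr = np.concatenate(rchunks) if rchunks else np.empty(0, dtype=np.uint32)
        order = np.argsort(allk, kind="stable")
        return cls(allk[order], allr[order], len(sequences), k)

    def shared_kmer_counts(self, seq: str) -> np.ndarray:
        """Vector of |k-spectrum(read) ∩ k-spectrum(seq)| for every read."""
        qk = sequence_kmers(seq, self.k)
        if qk.size == 0 or self._kmers.size == 0:
            return np.zeros(self.n_reads, dtype=np.int64)
        lo = np.searchsorted(self._kmers, qk, side="left")
        hi = np.searchsorted(self._kmers, qk, side="right")
        lens = hi - lo
        total = int(lens.sum())
        if total == 0:
            return np.zeros(self.n_reads, dtype=np.int64)
        # Gather self._reads[lo[i]:hi[i]] for all i without a Python loop.
        offsets = np.repeat(np.cumsum(lens) - lens, lens)
        idx = np.repeat(lo, lens) + (np.arange(total) - offsets)
        return np.bincount(self._reads[idx], minlength=self.n_reads).astype(np.int64)

    def similar_reads(self, seq: str, t: Union[int, float]) -> np.ndarray:
        """Reads satisfying the shared-k-mer similarity criterion.

        Ratio thresholds are relative to the query's distinct k-mers.
        """
        n_qk = int(sequence_kmers(seq, self.k).size)
        t_abs = resolve_threshold(t, n_qk)
        counts = self.shared_kmer_counts(seq)
        return np.flatnonzero(counts >= t_abs).astype(np.int64)


def compute_rates(
    reported: Mapping[str, np.ndarray], truth: Mapping[str, np.ndarray]
) -> dict:
    """Micro-averaged pair-level FPR/TPR plus per-query macro averages.

    FPR = (reported pairs not in truth) / (reported pairs);
    TPR = (truth pairs reported) / (truth pairs). Zero denominators give NaN
    with a warning.
    """
    n_reported = n_truth = n_fp = n_tp = 0
    macro_fpr: list[float] = []
    macro_tpr: list[float] = []
    for qid, rep in reported.items():
        rep = np.asarray(rep)
        tru = np.asarray(truth.get(qid, np.empty(0, dtype=np.int64)))
        tp = np.intersect1d(rep, tru).size
        n_reported += rep.size
        n_truth += tru.size
        n_tp += tp
        n_fp += rep.size - tp
        if rep.size:
            macro_fpr.append((rep.size - tp) / rep.size)
        if tru.size:
            macro_tpr.append(tp / tru.size)
    if n_reported == 0:
        warnings.warn("no reported pairs: FPR undefined")
        fpr = math.nan
    else:
        fpr = n_fp / n_reported
    if n_truth == 0:
        warnings.warn("no truth pairs: TPR undefined")
        tpr = math.nan
    else:
        tpr = n_tp / n_truth
    return {
        "fpr": fpr,
        "tpr": tpr,
        "n_reported_pairs": n_reported,
        "n_truth_pairs": n_truth,
        "n_queries": len(reported),
        "macro_fpr": float(np.mean(macro_fpr)) if macro_fpr else math.nan,
        "macro_tpr": float(np.mean(macro_tpr)) if macro_tpr else math.nan,
    }


def color_compression_fold(index: KmerReadIndex) -> float:
    """Size of raw 32-bit color lists divided by their delta+varint size."""
    raw = packed = 0
    for color in index.colors:
        raw += 4 * color.size
        packed += len(delta_encode(color))
    return raw / packed if packed else math.nan


def retrieval_experiment(
    seed: int,
    *,
    genome_length: int = 500_000,
    coverage: float = 50.0,
    read_length_mean: int = 10_000,
    error_rate: float = 0.01,
    n_queries: int = 1000,
    k: int = 31,
    m: int = 15,
    min_abundance: int = 2,
    max_abundance: int = 5000,
    counting: str = "exact",
    filter_log2_size: int = 26,
    ratio: float = 0.3,
    return_index: bool = False,
) -> dict:
    """One full FPR/TPR measurement at the configured scale.

    Simulates a read set, builds the index, runs positive queries at the
    ratio threshold over the query's indexed minimizers, and scores reported
    pairs against the oracle's shared-k-mer criterion at the matching ratio
    over the query's distinct k-mers.
    """
    config = SimulationConfig(
        genome_length=genome_length,
        coverage=coverage,
        read_length_mean=read_length_mean,
        error_rate=error_rate,
        rng_seed=seed,
    )
    genome = simulate_genome(config)
    reads, _ = simulate_reads(genome, config)
    params = IndexParams(
        k=k,
        m=m,
        min_abundance=min_abundance,
        max_abundance=max_abundance,
        filter_log2_size=filter_log2_size,
    )
    index = build_index([r.sequence for r in reads], params, counting=counting)
    oracle = OracleIndex.from_reads([r.sequence for r in reads], k)
    queries, _ = make_queries(genome, config, n_pos=n_queries, n_neg=0)
    reported = {}
    truth = {}
    for qid, seq in queries:
        res = query_candidates(index, seq, ratio, query_id=qid)
        reported[qid] = res.read_ids
        truth[qid] = oracle.similar_reads(seq, ratio)
    out = compute_rates(reported, truth)
    out.update(
        {
            "k": k,
            "m": m,
            "error_rate": error_rate,
            "coverage": coverage,
            "genome_length": genome_length,
            "counting": counting,
            "ratio": ratio,
            "n_reads": len(reads),
        }
    )
    if return_index:
        out["index"] = index
    return out


def no_false_negative_experiment(
    seed: int,
    *,
    genome_length: int = 100_000,
    coverage: float = 20.0,
    error_rate: float = 0.01,
    read_length_mean: int = 10_000,
    n_queries: int = 4,
    k: int = 31,
    m: int = 15,
    ratio: float = 0.3,
) -> dict:
    """Superset-guarantee check with abundance filtering disabled.

    Candidates are taken at the weakest threshold (one shared indexed
    minimizer); since every minimizer is indexed, any read sharing a k-mer
    with the query shares a minimizer and must be a candidate, so recall of
    oracle-similar reads is exactly 1. Verification at the oracle's k-mer
    threshold must then reproduce the oracle set exactly.
    """
    config = SimulationConfig(
        genome_length=genome_length,
        coverage=coverage,
        read_length_mean=read_length_mean,
        error_rate=error_rate,
        rng_seed=seed,
    )
    genome = simulate_genome(config)
    reads, _ = simulate_reads(genome, config)
    seqs = [r.sequence for r in reads]
    params = IndexParams(k=k, m=m, min_abundance=1, max_abundance=2**31 - 1)
    index = build_index(seqs, params, counting="none")
    oracle = OracleIndex.from_reads(seqs, k)
    queries, _ = make_queries(genome, config, n_pos=n_queries, n_neg=0)
    reported = {}
    truth = {}
    verified_exact = True
    for qid, seq in queries:
        res = query_candidates(index, seq, 1, query_id=qid)
        reported[qid] = res.read_ids
        truth[qid] = oracle.similar_reads(seq, ratio)
        ver = verify_hits(index, seqs, res, ratio)
        if not np.array_equal(ver.read_ids, truth[qid]):
            verified_exact = False
    rates = compute_rates(reported, truth)
    return {
        "tpr": rates["tpr"],
        "verified_exact": verified_exact,
        "n_truth_pairs": rates["n_truth_pairs"],
        "n_reported_pairs": rates["n_reported_pairs"],
        "n_queries": n_queries,
    }


def write_metrics_tsv(path, rows: Sequence[dict], columns: Optional[list] = None):
    """Write experiment metric dicts as a TSV table."""
    if not rows:
        raise ValueError("no metric rows to write")
    if columns is None:
        columns = [c for c in rows[0] if c != "index"]
    with open(path, "w") as fh:
        fh.write("# fpr = false reported pairs / reported pairs; "
                 "tpr = reported truth pairs / truth pairs (pair-level, micro)\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
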