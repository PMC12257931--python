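"""Canonical k-mers and minimizer selection for DNA sequences.

A k-mer is represented by its canonical form: the lexicographically smaller
of the k-mer and its reverse complement (A < C < G < T). The m-minimizer of a
k-mer is the smallest of its canonical m-mers under a seeded pseudo-random
order (a 64-bit mixing hash of the 2-bit-packed m-mer); a pure lexicographic
order is also exposed so that hand-checkable examples exist.

All heavy routines operate on numpy arrays of 2-bit base codes and return
packed integer k-mers/m-mers (``uint64``), which keeps whole-read
decomposition vectorized. Strings are accepted at every public entry point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

U64 = np.uint64
_U64_MAX = U64(0xFFFFFFFFFFFFFFFF)

# 2-bit encoding: A=0, C=1, G=2, T=3 so that packed integer order equals
# lexicographic order. 255 marks any non-ACGT byte.
_INVALID = 255
_ENCODE = np.full(256, _INVALID, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTacgt", "TGCATGCA")


@dataclass(frozen=True)
class IndexParams:
    """Build-time constants of a minimizer-tinted index.

    Parameters
    ----------
    k : length of indexed k-mers (bases); at most 31 so a canonical k-mer
        packs into 64 bits. Odd k avoids palindromic canonical k-mers.
    m : minimizer length (bases), ``m <= k``.
    min_abundance : minimum read-level abundance (number of reads containing
        the minimizer) for a minimizer to be "solid", inclusive.
    max_abundance : maximum abundance for solidity, inclusive; over-abundant
        minimizers (typically repeats) are excluded at lookup time.
    filter_log2_size : log2 of the number of counting-filter slots.
    hash_seed : seed of the minimizer order and of the counting-filter hash;
        stored in the index header so an index is reproducible.
    threshold_mode : default interpretation of query thresholds, "ratio"
        (fraction of the query's indexed minimizers) or "absolute".
    """

    k: int = 31
    m: int = 15
    min_abundance: int = 2
    max_abundance: int = 5000
    filter_log2_size: int = 26
    hash_seed: int = 0x51A5_C0DE
    threshold_mode: str = "ratio"

    def __post_init__(self) -> None:
        if not (0 < self.m <= self.k):
            raise ValueError(f"require 0 < m <= k, got m={self.m}, k={self.k}")
        if self.k > 31:
            raise ValueError("k > 31 not supported (2-bit packing into 64 bits)")
        if not (1 <= self.min_abundance <= self.max_abundance):
            raise ValueError(
                "require 1 <= min_abundance <= max_abundance, got "
                f"[{self.min_abundance}, {self.max_abundance}]"
            )
        if not (16 <= self.filter_log2_size <= 40):
            raise ValueError("filter_log2_size must lie in [16, 40]")
        if self.threshold_mode not in ("absolute", "ratio"):
            raise ValueError("threshold_mode must be 'absolute' or 'ratio'")

    @property
    def window(self) -> int:
        """Number of m-mer positions inside one k-mer."""
        return self.k - self.m + 1


def encode_sequence(seq: Union[str, bytes, np.ndarray]) -> np.ndarray:
    """Return the 2-bit code array of *seq*; non-ACGT bytes become 255."""
    if isinstance(seq, np.ndarray):
        return seq
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode_kmer(value: int, length: int) -> str:
    """Unpack a 2-bit-packed k-mer integer back into a string."""
    value = int(value)
    out = bytearray(length)
    for i in range(length - 1, -1, -1):
        out[i] = _BASES[value & 3]
        value >>= 2
    return out.decode("ascii")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; rejects non-ACGT characters."""
    codes = encode_sequence(seq)
    if (codes == _INVALID).any():
        bad = seq[int(np.argmax(codes == _INVALID))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return seq.translate(_RC_TABLE)[::-1]


def canonicalize(kmer: str, k: int | None = None) -> str:
    """Lexicographically smaller of *kmer* and its reverse complement."""
    if k is not None and len(kmer) != k:
        raise ValueError(f"expected a {k}-mer, got length {len(kmer)}")
    rc = reverse_complement(kmer)
    return min(kmer.upper(), rc.upper())


def mix64(values: np.ndarray | int, seed: int) -> np.ndarray:
    """Seeded splitmix64 finalizer; a bijection on 64-bit integers.

    Defines the pseudo-random minimizer order: m-mer x precedes y iff
    mix64(x) < mix64(y).
    """
    with np.errstate(over="ignore"):  # 64-bit wrap-around is the point
        z = np.asarray(values, dtype=U64) ^ U64(seed & 0xFFFFFFFFFFFFFFFF)
        z = z + U64(0x9E3779B97F4A7C15)
        z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
        return z ^ (z >> U64(31))


def _windowed_values(codes: np.ndarray, w: int, block: int = 1 << 17) -> np.ndarray:
    """Packed integer value of every w-window of *codes* (invalid bases as 0)."""
    n = codes.size - w + 1
    out = np.empty(n, dtype=U64)
    pows = U64(4) ** np.arange(w - 1, -1, -1, dtype=U64)
    x = codes.astype(U64)
    for s in range(0, n, block):
        e = min(n, s + block)
        win = sliding_window_view(x[s : e + w - 1], w)
        out[s:e] = (win * pows).sum(axis=1)
    return out


def canonical_window_values(
    codes: np.ndarray, w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical packed values of all w-mers of a code array.

    Returns ``(values, valid)`` where ``values[i]`` is the packed canonical
    w-mer starting at position i and ``valid[i]`` is False when the window
    contains a non-ACGT base (its value is meaningless and must be masked).
    """
    if codes.size < w:
        return np.empty(0, dtype=U64), np.empty(0, dtype=bool)
    valid = codes != _INVALID
    safe = np.where(valid, codes, 0).astype(np.uint8)
    fwd = _windowed_values(safe, w)
    comp = (3 - safe).astype(np.uint8)
    rc = _windowed_values(comp[::-1], w)[::-1]
    vals = np.minimum(fwd, rc)
    win_valid = sliding_window_view(valid, w).all(axis=1)
    return vals, win_valid


def sequence_kmers(seq: Union[str, np.ndarray], k: int) -> np.ndarray:
    """Sorted distinct canonical k-mers (packed) of *seq* — its k-spectrum."""
    vals, valid = canonical_window_values(encode_sequence(seq), k)
    return np.unique(vals[valid])


def _minimizer_windows(
    codes: np.ndarray, params: IndexParams, order: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-k-mer minimizer values, their positions, and k-window validity."""
    k, m = params.k, params.m
    mvals, mvalid = canonical_window_values(codes, m)
    if codes.size < k:
        empty = np.empty(0, dtype=U64)
        return empty, np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    if order == "hash":
        keys = mix64(mvals, params.hash_seed)
    elif order == "lex":
        keys = mvals.copy()
    else:
        raise ValueError(f"unknown minimizer order {order!r}")
    # Invalid m-windows can never win; k-windows touching them are dropped
    # wholesale below.
    keys[~mvalid] = _U64_MAX
    w = params.window
    arg = sliding_window_view(keys, w).argmin(axis=1)  # leftmost minimum
    pos = np.arange(arg.size, dtype=np.int64) + arg
    kvalid = sliding_window_view(mvalid, w).all(axis=1)
    return mvals[pos], pos, kvalid


def minimizer_of_kmer(kmer: str, params: IndexParams, order: str = "hash") -> str:
    """Canonical m-minimizer of a single k-mer, as a string.

    Considers both strands of every m-mer; ties under the order are broken by
    leftmost position. Strand-invariant by construction.
    """
    if len(kmer) != params.k:
        raise ValueError(f"expected a {params.k}-mer, got length {len(kmer)}")
    vals, _, kvalid = _minimizer_windows(encode_sequence(kmer), params, order)
    if not kvalid[0]:
        raise ValueError("k-mer contains a non-ACGT character")
    return decode_kmer(vals[0], params.m)


def sequence_minimizers(
    seq: Union[str, np.ndarray],
    params: IndexParams,
    distinct: bool = True,
    order: str = "hash",
    return_positions: bool = False,
):
    """Minimizers of every valid k-mer of *seq*.

    With ``distinct=True`` (default) returns the sorted set of packed
    canonical minimizers; otherwise the per-k-mer multiset in window order.
    Windows containing a non-ACGT base contribute nothing; sequences shorter
    than k yield an empty result. With ``return_positions=True`` also returns
    the (distinct) selected minimizer start positions, used for density
    diagnostics.
    """
    vals, pos, kvalid = _minimizer_windows(encode_sequence(seq), params, order)
    vals, pos = vals[kvalid], pos[kvalid]
    if distinct:
        vals = np.unique(vals)
        pos = np.unique(pos)
    if return_positions:
        return vals, pos
    return vals
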