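"""Approximate minimizer counting and solid/weak classification.

Sequencing errors create rare, mostly unique k-mers. Rather than counting
k-mers, abundance is tracked at the minimizer level (an order of magnitude
fewer keys): a minimizer is *solid* when its read-level abundance lies inside
``[min_abundance, max_abundance]`` and only solid minimizers are indexed.
If a k-mer is sufficiently abundant, so is its minimizer, hence minimizer
filtering never discards a solid k-mer's key.

The :class:`CountingFilter` is a single-row count-min sketch: one seeded hash
slot per key, saturating counters. Colliding keys share a counter, so a
reported count is *never below* the true count — at the lower abundance bound
collisions can only admit extra minimizers, at the upper bound they can evict
genuine ones. :class:`ExactCounter` is the collision-free reference used as
an oracle and for exact-counting builds.
"""

from __future__ import annotations

import numpy as np

from .kmer_minimizer import IndexParams, mix64

U64 = np.uint64

# Decorrelates the filter's slot hash from the minimizer order.
_FILTER_SALT = 0xA5A5_5A5A_0F0F_F0F0

_COUNTER_MAX = np.iinfo(np.uint16).max


class CountingFilter:
    """Fixed-size saturating counter array addressed by a seeded hash.

    Counters are 16-bit and capped at ``max_abundance + 1`` (one past the
    upper bound is enough to decide solidity, and caps memory growth).
    """

    def __init__(self, log2_size: int, hash_seed: int, max_abundance: int):
        if not (16 <= log2_size <= 40):
            raise ValueError("log2_size must lie in [16, 40]")
        self.log2_size = log2_size
        self.hash_seed = hash_seed
        self.cap = np.uint16(min(max_abundance + 1, _COUNTER_MAX))
        self._mask = U64((1 << log2_size) - 1)
        self.counters = np.zeros(1 << log2_size, dtype=np.uint16)

    @classmethod
    def from_params(cls, params: IndexParams) -> "CountingFilter":
        return cls(params.filter_log2_size, params.hash_seed, params.max_abundance)

    def slots(self, minimizers) -> np.ndarray:
        """Counter slot of each minimizer (exposed for collision tests)."""
        h = mix64(np.asarray(minimizers, dtype=U64), self.hash_seed ^ _FILTER_SALT)
        return (h & self._mask).astype(np.int64)

    def add(self, minimizers: np.ndarray) -> None:
        """Increment the counter of every minimizer in the batch by one.

        Batches are expected to be per-read distinct minimizer sets, so a
        slot gains at most a few units per call; saturation is re-applied
        after the batch.
        """
        s = self.slots(minimizers)
        np.add.at(self.counters, s, 1)
        self.counters[s] = np.minimum(self.counters[s], self.cap)

    def increment(self, minimizer: int) -> None:
        self.add(np.asarray([minimizer], dtype=U64))

    def counts(self, minimizers) -> np.ndarray:
        """Reported counts; >= true counts, saturated at ``cap``."""
        return self.counters[self.slots(minimizers)]

    def count(self, minimizer: int) -> int:
        return int(self.counts(np.asarray([minimizer], dtype=U64))[0])


class ExactCounter:
    """Exact multiset counter over minimizer keys (the collision-free oracle).

    Accumulates per-read distinct minimizer arrays and resolves counts via a
    sorted unique-key table on first lookup.
    """

    def __init__(self) -> None:
        self._chunks: list[np.ndarray] = []
        self._keys: np.ndarray | None = None
        self._counts: np.ndarray | None = None

    def add(self, minimizers: np.ndarray) -> None:
        if self._keys is not None:
            raise RuntimeError("counter already finalized")
        self._chunks.append(np.asarray(minimizers, dtype=U64))

    def increment(self, minimizer: int) -> None:
        self.add(np.asarray([minimizer], dtype=U64))

    def _finalize(self) -> None:
        if self._keys is None:
            if self._chunks:
                allm = np.concatenate(self._chunks)
            else:
                allm = np.empty(0, dtype=U64)
            self._keys, self._counts = np.unique(allm, return_counts=True)
            self._chunks = []

    def counts(self, minimizers) -> np.ndarray:
        self._finalize()
        q = np.asarray(minimizers, dtype=U64)
        idx = np.searchsorted(self._keys, q).clip(max=max(self._keys.size - 1, 0))
        out = np.zeros(q.size, dtype=np.int64)
        if self._keys.size:
            hit = self._keys[idx] == q
            out[hit] = self._counts[idx[hit]]
        return out

    def count(self, minimizer: int) -> int:
        return int(self.counts(np.asarray([minimizer], dtype=U64))[0])


def is_solid(count, params: IndexParams):
    """True iff ``min_abundance <= count <= max_abundance`` (vectorized)."""
    c = np.asarray(count)
    res = (c >= params.min_abundance) & (c <= params.max_abundance)
    return bool(res) if res.ndim == 0 else res


def make_counter(params: IndexParams, mode: str):
    """Counter factory: 'filter' (approximate), 'exact', or 'none'."""
    if mode == "filter":
        return CountingFilter.from_params(params)
    if mode == "exact":
        return ExactCounter()
    if mode == "none":
        return None
    raise ValueError(f"unknown counting mode {mode!r}")
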