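"""Building the minimizer-tinted de Bruijn graph index.

The index maps every solid minimizer of a read set to a *color*: the sorted,
deduplicated list of read identifiers containing a k-mer with that minimizer.
Because overlapping reads share long runs of k-mers, distinct colors are few
(on error-free data roughly one new combination per read start/end), so
colors are interned in a :class:`ColorTable` that stores each distinct list
exactly once and minimizers reference them by color id. On disk, color lists
are delta-encoded and varint-packed (sorted ids differ by small gaps at
sequencing-like coverage, giving a several-fold size reduction over raw
32-bit ids).

Build is two logical passes sharing one decomposition: per read, the distinct
minimizer set is computed once; pass 1 feeds abundance counting (approximate
counting filter, exact dictionary, or none), pass 2 keeps solid minimizers
and accumulates read ids per minimizer. The upper abundance bound is applied
at pass-2 lookup, mirroring exclusion of over-abundant keys.
"""

from __future__ import annotations

import gzip
import io
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

from .abundance_filter import make_counter
from .kmer_minimizer import IndexParams, sequence_minimizers

U64 = np.uint64

MAGIC = b"TDBG"
FORMAT_VERSION = 1


class IndexFormatError(ValueError):
    """Base class for malformed index files."""


class IndexMagicError(IndexFormatError):
    pass


class IndexVersionError(IndexFormatError):
    pass


class IndexTruncatedError(IndexFormatError):
    pass


@dataclass
class ReadRecord:
    """One input read: dense 0-based id, sequence, optional source offset."""

    read_id: int
    sequence: str
    source_offset: Optional[int] = None


# ---------------------------------------------------------------------------
# Input parsing


def _open_maybe_gzip(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def sequence_format(path: Union[str, Path]) -> str:
    """'fasta' or 'fastq' from the file extension (ignoring .gz)."""
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    ext = Path(name).suffix.lower()
    if ext in (".fa", ".fasta", ".fna"):
        return "fasta"
    if ext in (".fq", ".fastq"):
        return "fastq"
    raise ValueError(f"cannot infer FASTA/FASTQ format from {path!s}")


def scan_record_offsets(path: Union[str, Path]) -> list[int]:
    """Byte offset of each record start in an uncompressed FASTA/FASTQ file.

    Used so the verification stage can seek straight to a candidate read
    instead of re-scanning the whole file. Parsing proper stays with SeqIO.
    """
    fmt = sequence_format(path)
    offsets: list[int] = []
    with open(path, "rb") as fh:
        if fmt == "fasta":
            pos = fh.tell()
            for line in iter(fh.readline, b""):
                if line.startswith(b">"):
                    offsets.append(pos)
                pos = fh.tell()
        else:  # fastq: records are 4 lines
            i = 0
            pos = fh.tell()
            for line in iter(fh.readline, b""):
                if i % 4 == 0:
                    offsets.append(pos)
                i += 1
                pos = fh.tell()
    return offsets


def read_sequences(
    path: Union[str, Path], record_offsets: bool = True
) -> Iterator[ReadRecord]:
    """Stream reads from a FASTA/FASTQ file (optionally gzip-compressed).

    Record order defines the dense read id. Offsets are recorded for plain
    (uncompressed) files unless disabled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"read file not found: {path}")
    fmt = sequence_format(path)
    offsets: Optional[list[int]] = None
    if record_offsets and path.suffix != ".gz":
        offsets = scan_record_offsets(path)
    with _open_maybe_gzip(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, fmt)):
            off = offsets[i] if offsets is not None else None
            yield ReadRecord(i, str(rec.seq).upper(), off)


def fetch_read(path: Union[str, Path], offset: int) -> str:
    """Fetch one read sequence from an uncompressed file by record offset."""
    fmt = sequence_format(path)
    with open(path, "rt") as fh:
        fh.seek(offset)
        rec = next(SeqIO.parse(fh, fmt))
        return str(rec.seq).upper()


# ---------------------------------------------------------------------------
# Delta + varint codec


def delta_encode(ids: Sequence[int] | np.ndarray) -> bytes:
    """Encode a strictly increasing id list: first value absolute, then
    successive differences, each as a LEB128 varint."""
    arr = np.asarray(ids, dtype=np.int64)
    if arr.size == 0:
        return b""
    if arr.size > 1 and not (np.diff(arr) > 0).all():
        raise ValueError("ids must be strictly increasing")
    if arr[0] < 0:
        raise ValueError("ids must be non-negative")
    deltas = np.empty(arr.size, dtype=np.int64)
    deltas[0] = arr[0]
    np.subtract(arr[1:], arr[:-1], out=deltas[1:])
    out = bytearray()
    for d in deltas.tolist():
        while d >= 0x80:
            out.append((d & 0x7F) | 0x80)
            d >>= 7
        out.append(d)
    return bytes(out)


def delta_decode(payload: bytes) -> np.ndarray:
    """Invert :func:`delta_encode`; returns a uint32 array."""
    values = []
    acc = 0
    shift = 0
    for b in payload:
        acc |= (b & 0x7F) << shift
        if b & 0x80:
            shift += 7
        else:
            values.append(acc)
            acc = 0
            shift = 0
    if shift != 0:
        raise IndexTruncatedError("varint payload ends mid-value")
    if not values:
        return np.empty(0, dtype=np.uint32)
    return np.cumsum(np.asarray(values, dtype=np.int64)).astype(np.uint32)


# ---------------------------------------------------------------------------
# Color table


class ColorTable:
    """Bidirectional map between color ids and distinct sorted read-id lists.

    Content-addressed: interning an already-present list (byte-wise equality
    of the packed uint32 array) returns its existing id, so every distinct
    color is stored exactly once.
    """

    def __init__(self) -> None:
        self._colors: list[np.ndarray] = []
        self._ids: dict[bytes, int] = {}

    def __len__(self) -> int:
        return len(self._colors)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self._colors)

    def intern(self, ids: Sequence[int] | np.ndarray) -> int:
        arr = np.ascontiguousarray(ids, dtype=np.uint32)
        if arr.size == 0:
            raise ValueError("a color must be non-empty")
        if arr.size > 1 and not (np.diff(arr.astype(np.int64)) > 0).all():
            raise ValueError("a color must be strictly increasing")
        key = arr.tobytes()
        cid = self._ids.get(key)
        if cid is None:
            cid = len(self._colors)
            self._ids[key] = cid
            self._colors.append(arr)
        return cid

    def color(self, color_id: int) -> np.ndarray:
        return self._colors[color_id]

    def color_id(self, ids: Sequence[int] | np.ndarray) -> Optional[int]:
        arr = np.ascontiguousarray(ids, dtype=np.uint32)
        return self._ids.get(arr.tobytes())


# ---------------------------------------------------------------------------
# The index


@dataclass
class KmerReadIndex:
    """Minimizer -> color-id map plus the color table and build parameters.

    ``_keys`` is the sorted array of solid minimizers and ``_cids`` the
    parallel color ids; lookups are binary searches.
    """

    params: IndexParams
    n_reads: int
    colors: ColorTable
    _keys: np.ndarray = field(repr=False)
    _cids: np.ndarray = field(repr=False)
    read_offsets: Optional[np.ndarray] = None
    source_path: Optional[str] = None

    @property
    def n_minimizers(self) -> int:
        return int(self._keys.size)

    @property
    def minimizer_map(self) -> dict[int, int]:
        """Dense dict view (small indexes / tests only)."""
        return dict(zip(self._keys.tolist(), self._cids.tolist()))

    def get_color_id(self, minimizer: int) -> Optional[int]:
        i = int(np.searchsorted(self._keys, U64(minimizer)))
        if i < self._keys.size and self._keys[i] == U64(minimizer):
            return int(self._cids[i])
        return None

    def color(self, color_id: int) -> np.ndarray:
        return self.colors.color(color_id)

    def reads_with_minimizer(self, minimizer: int) -> np.ndarray:
        cid = self.get_color_id(minimizer)
        if cid is None:
            return np.empty(0, dtype=np.uint32)
        return self.colors.color(cid)

    def lookup(self, minimizers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized lookup: (mask of found minimizers, their color ids)."""
        q = np.asarray(minimizers, dtype=U64)
        if self._keys.size == 0 or q.size == 0:
            return np.zeros(q.size, dtype=bool), np.empty(0, dtype=np.uint32)
        idx = np.searchsorted(self._keys, q).clip(max=self._keys.size - 1)
        found = self._keys[idx] == q
        return found, self._cids[idx[found]]

    def save(self, path: Union[str, Path]) -> None:
        save_index(self, path)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "KmerReadIndex":
        return load_index(path)


def build_index(
    reads: Iterable[Union[ReadRecord, str]],
    params: IndexParams,
    counting: str = "filter",
) -> KmerReadIndex:
    """Build the minimizer-tinted index from a read stream.

    ``counting`` selects abundance tracking: "filter" (the counting filter,
    default), "exact" (collision-free), or "none" (skip filtering entirely —
    every minimizer is solid). Abundance is per-read: each read contributes
    each of its distinct minimizers once, so abundance tracks coverage.
    """
    per_read: list[np.ndarray] = []
    offsets: list[Optional[int]] = []
    for i, rec in enumerate(reads):
        if isinstance(rec, str):
            rec = ReadRecord(i, rec)
        if rec.read_id != i:
            raise ValueError(f"read ids must be dense 0..N-1, got {rec.read_id} at {i}")
        per_read.append(sequence_minimizers(rec.sequence, params, distinct=True))
        offsets.append(rec.source_offset)
    if not per_read:
        raise ValueError("empty input: no reads to index")

    counter = make_counter(params, counting)
    if counter is not None:
        for mins in per_read:
            counter.add(mins)

    solid_chunks: list[np.ndarray] = []
    rid_chunks: list[np.ndarray] = []
    for rid, mins in enumerate(per_read):
        if counter is not None:
            c = counter.counts(mins)
            mins = mins[(c >= params.min_abundance) & (c <= params.max_abundance)]
        solid_chunks.append(mins)
        rid_chunks.append(np.full(mins.size, rid, dtype=np.uint32))

    allm = np.concatenate(solid_chunks) if solid_chunks else np.empty(0, dtype=U64)
    allr = np.concatenate(rid_chunks) if rid_chunks else np.empty(0, dtype=np.uint32)
    order = np.argsort(allm, kind="stable")  # stable keeps read ids increasing
    allm, allr = allm[order], allr[order]

    colors = ColorTable()
    if allm.size:
        bounds = np.flatnonzero(np.diff(allm)) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [allm.size]))
        keys = allm[starts]
        cids = np.empty(keys.size, dtype=np.uint32)
        for j, (a, b) in enumerate(zip(starts.tolist(), ends.tolist())):
            cids[j] = colors.intern(allr[a:b])
    else:
        keys = np.empty(0, dtype=U64)
        cids = np.empty(0, dtype=np.uint32)

    have_offsets = all(o is not None for o in offsets) and len(offsets) > 0
    return KmerReadIndex(
        params=params,
        n_reads=len(per_read),
        colors=colors,
        _keys=keys,
        _cids=cids,
        read_offsets=np.asarray(offsets, dtype=np.uint64) if have_offsets else None,
        source_path=None,
    )


def build_index_from_file(
    path: Union[str, Path],
    params: IndexParams,
    counting: str = "filter",
    record_offsets: bool = True,
) -> KmerReadIndex:
    """Build from a FASTA/FASTQ file, remembering the source path."""
    try:
        index = build_index(read_sequences(path, record_offsets), params, counting)
    except (OSError, ValueError) as exc:
        raise type(exc)(f"while indexing {path!s}: {exc}") from exc
    index.source_path = str(path)
    return index


# ---------------------------------------------------------------------------
# Serialization

_HEADER = struct.Struct("<4sBBBqqBqIBQQ")
# magic, version, k, m, min_ab, max_ab, filter_log2, hash_seed, n_reads,
# flags, n_minimizers, n_colors

_FLAG_OFFSETS = 1
_FLAG_SOURCE = 2


def save_index(index: KmerReadIndex, path: Union[str, Path]) -> None:
    """Write the index; byte-identical for identical input, params and seed."""
    p = index.params
    flags = 0
    if index.read_offsets is not None:
        flags |= _FLAG_OFFSETS
    if index.source_path is not None:
        flags |= _FLAG_SOURCE
    with open(path, "wb") as fh:
        fh.write(
            _HEADER.pack(
                MAGIC,
                FORMAT_VERSION,
                p.k,
                p.m,
                p.min_abundance,
                p.max_abundance,
                p.filter_log2_size,
                p.hash_seed,
                index.n_reads,
                flags,
                index._keys.size,
                len(index.colors),
            )
        )
        fh.write(np.uint8(0 if p.threshold_mode == "absolute" else 1).tobytes())
        fh.write(np.ascontiguousarray(index._keys, dtype=U64).tobytes())
        fh.write(np.ascontiguousarray(index._cids, dtype=np.uint32).tobytes())
        for color in index.colors:
            payload = delta_encode(color)
            fh.write(struct.pack("<I", len(payload)))
            fh.write(payload)
        if flags & _FLAG_OFFSETS:
            fh.write(struct.pack("<Q", index.read_offsets.size))
            fh.write(np.ascontiguousarray(index.read_offsets, dtype=U64).tobytes())
        if flags & _FLAG_SOURCE:
            src = index.source_path.encode("utf-8")
            fh.write(struct.pack("<H", len(src)))
            fh.write(src)


def _read_exact(fh: io.BufferedReader, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise IndexTruncatedError(
            f"index file truncated: wanted {n} bytes, got {len(data)}"
        )
    return data


def load_index(path: Union[str, Path]) -> KmerReadIndex:
    """Load an index written by :func:`save_index`.

    Raises :class:`IndexMagicError`, :class:`IndexVersionError` or
    :class:`IndexTruncatedError` on malformed files.
    """
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) < 4 or head[:4] != MAGIC:
            raise IndexMagicError(f"not an index file (bad magic): {path!s}")
        if len(head) != _HEADER.size:
            raise IndexTruncatedError(f"index header truncated: {path!s}")
        (
            _,
            version,
            k,
            m,
            min_ab,
            max_ab,
            flog2,
            seed,
            n_reads,
            flags,
            n_min,
            n_colors,
        ) = _HEADER.unpack(head)
        if version != FORMAT_VERSION:
            raise IndexVersionError(
                f"unsupported index version {version} (expected {FORMAT_VERSION})"
            )
        tmode = "absolute" if _read_exact(fh, 1)[0] == 0 else "ratio"
        params = IndexParams(
            k=k,
            m=m,
            min_abundance=min_ab,
            max_abundance=max_ab,
            filter_log2_size=flog2,
            hash_seed=seed,
            threshold_mode=tmode,
        )
        keys = np.frombuffer(_read_exact(fh, 8 * n_min), dtype=U64).copy()
        cids = np.frombuffer(_read_exact(fh, 4 * n_min), dtype=np.uint32).copy()
        colors = ColorTable()
        for _ in range(n_colors):
            (plen,) = struct.unpack("<I", _read_exact(fh, 4))
            colors.intern(delta_decode(_read_exact(fh, plen)))
        read_offsets = None
        if flags & _FLAG_OFFSETS:
            (n_off,) = struct.unpack("<Q", _read_exact(fh, 8))
            read_offsets = np.frombuffer(_read_exact(fh, 8 * n_off), dtype=U64).copy()
        source_path = None
        if flags & _FLAG_SOURCE:
            (slen,) = struct.unpack("<H", _read_exact(fh, 2))
            source_path = _read_exact(fh, slen).decode("utf-8")
    return KmerReadIndex(
        params=params,
        n_reads=n_reads,
        colors=colors,
        _keys=keys,
        _cids=cids,
        read_offsets=read_offsets,
        source_path=source_path,
    )
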