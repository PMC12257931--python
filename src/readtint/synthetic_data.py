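"""Synthetic genomes, long-read datasets and query batches with ground truth.

Emulates the statistical structure of whole-genome long-read sequencing so
the index and its evaluation are testable without downloads: an i.i.d.
random genome; reads drawn uniformly along it (normal length distribution
with a floor, truncated at the genome end) until the target coverage is
reached, sampled from both strands, with independent per-base errors split
between substitutions, insertions and deletions; and query batches mixing
*positive* queries (error-free genome substrings) with *negative* queries
(i.i.d. random sequences of matched lengths).

Everything is deterministic under ``rng_seed``; each stage draws from its
own salted substream, so e.g. the genome does not change when the read
parameters do.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .index_builder import ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Experimental design of one simulated sequencing run.

    Defaults match the study conditions reproduced by the evaluation module:
    a 500 kb genome at 50X coverage, ~10 kb reads, 1% per-base errors with a
    substitution-heavy 80/10/10 error mix.
    """

    genome_length: int = 500_000
    coverage: float = 50.0
    read_length_mean: int = 10_000
    read_length_spread: int = 1_000
    error_rate: float = 0.01
    error_mix: tuple[float, float, float] = (0.8, 0.1, 0.1)  # sub, ins, del
    rng_seed: int = 0
    min_read_length: int = 200

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0.0 <= self.error_rate <= 0.3):
            raise ValueError("error_rate must lie in [0, 0.3]")
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ValueError("error_mix fractions must sum to 1")


@dataclass(frozen=True)
class ReadOrigin:
    """Ground-truth origin interval [start, end) of a read on the genome."""

    read_id: int
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class QueryOrigin:
    """Origin interval of a positive query; start is None for negatives."""

    query_id: str
    start: Optional[int]
    end: Optional[int]


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, salt])


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def random_dna(length: int, rng: np.random.Generator) -> str:
    return _decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def simulate_genome(config: SimulationConfig) -> str:
    """I.i.d. uniform ACGT genome of the configured length (linear)."""
    return random_dna(config.genome_length, _rng(config, 1))


def apply_errors(
    codes: np.ndarray, rng: np.random.Generator, rate: float, mix: Sequence[float]
) -> np.ndarray:
    """Independent per-base errors on a 2-bit code array.

    Substitutions change the base to one of the three others; insertions add
    a random base after the position; deletions remove it.
    """
    if rate == 0.0 or codes.size == 0:
        return codes
    pos = np.flatnonzero(rng.random(codes.size) < rate)
    if pos.size == 0:
        return codes
    kinds = rng.choice(3, size=pos.size, p=list(mix))
    out = codes.copy()
    sub = pos[kinds == 0]
    out[sub] = (out[sub] + rng.integers(1, 4, size=sub.size, dtype=np.uint8)) % 4
    dele = pos[kinds == 2]
    ins = pos[kinds == 1]
    out = np.delete(out, dele)
    # Remap insertion positions onto the post-deletion coordinates.
    ins_new = ins - np.searchsorted(dele, ins)
    out = np.insert(out, ins_new, rng.integers(0, 4, size=ins.size, dtype=np.uint8))
    return out


def simulate_reads(
    genome: str, config: SimulationConfig
) -> tuple[list[ReadRecord], list[ReadOrigin]]:
    """Sample reads until total bases reach ``coverage * genome_length``.

    Start positions are uniform; a read running past the genome end is
    truncated there (linear genome). Each read is taken from either strand
    with probability 1/2, then per-base errors are applied.
    """
    rng = _rng(config, 2)
    gcodes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    lut[np.frombuffer(b"ACGT", np.uint8)] = np.arange(4, dtype=np.uint8)
    gcodes = lut[gcodes]
    L = config.genome_length
    target = config.coverage * L
    total = 0
    reads: list[ReadRecord] = []
    origins: list[ReadOrigin] = []
    rid = 0
    while total < target:
        length = int(round(rng.normal(config.read_length_mean, config.read_length_spread)))
        length = max(config.min_read_length, min(length, L))
        start = int(rng.integers(0, L))
        end = min(start + length, L)
        if end - start < config.min_read_length:
            continue
        codes = gcodes[start:end]
        strand = "+"
        if rng.random() < 0.5:
            strand = "-"
            codes = (3 - codes)[::-1]
        codes = apply_errors(codes, rng, config.error_rate, config.error_mix)
        seq = _decode(codes)
        reads.append(ReadRecord(rid, seq))
        origins.append(ReadOrigin(rid, start, end, strand))
        total += len(seq)
        rid += 1
    return reads, origins


def make_queries(
    genome: str,
    config: SimulationConfig,
    n_pos: int,
    n_neg: int,
    length_range: tuple[int, int] = (500, 10_000),
) -> tuple[list[tuple[str, str]], list[QueryOrigin]]:
    """Positive (error-free genome substrings) and negative (random) queries.

    Lengths are uniform in ``length_range``, capped by the genome length.
    Returns ``[(query_id, sequence), ...]`` and the matching ground truth.
    """
    rng = _rng(config, 3)
    L = len(genome)
    lo = min(length_range[0], L)
    hi = min(length_range[1], L)
    queries: list[tuple[str, str]] = []
    origins: list[QueryOrigin] = []
    for i in range(n_pos):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, L - length + 1))
        qid = f"pos{i}"
        queries.append((qid, genome[start : start + length]))
        origins.append(QueryOrigin(qid, start, start + length))
    for i in range(n_neg):
        length = int(rng.integers(lo, hi + 1))
        qid = f"neg{i}"
        queries.append((qid, random_dna(length, rng)))
        origins.append(QueryOrigin(qid, None, None))
    return queries, origins


# ---------------------------------------------------------------------------
# File output


def write_fasta(path: Union[str, Path], items: Iterable[tuple[str, str]]) -> None:
    records = (SeqRecord(Seq(seq), id=str(name), description="") for name, seq in items)
    SeqIO.write(records, str(path), "fasta")


def write_read_truth(path: Union[str, Path], origins: Sequence[ReadOrigin]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tend\tstrand\n")
        for o in origins:
            fh.write(f"{o.read_id}\t{o.start}\t{o.end}\t{o.strand}\n")


def write_query_truth(path: Union[str, Path], origins: Sequence[QueryOrigin]) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tstart\tend\n")
        for o in origins:
            s = "" if o.start is None else o.start
            e = "" if o.end is None else o.end
            fh.write(f"{o.query_id}\t{s}\t{e}\n")


def write_dataset(
    outdir: Union[str, Path],
    config: SimulationConfig,
    n_pos: int = 100,
    n_neg: int = 100,
) -> dict[str, Path]:
    """Simulate and write genome.fa, reads.fa, queries.fa and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    reads, read_origins = simulate_reads(genome, config)
    queries, query_origins = make_queries(genome, config, n_pos, n_neg)
    paths = {
        "genome": outdir / "genome.fa",
        "reads": outdir / "reads.fa",
        "queries": outdir / "queries.fa",
        "read_truth": outdir / "reads_truth.tsv",
        "query_truth": outdir / "queries_truth.tsv",
    }
    write_fasta(paths["genome"], [("genome", genome)])
    write_fasta(paths["reads"], [(f"read{r.read_id}", r.sequence) for r in reads])
    write_fasta(paths["queries"], queries)
    write_read_truth(paths["read_truth"], read_origins)
    write_query_truth(paths["query_truth"], query_origins)
    return paths
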