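"""Index construction, color interning, codec and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readtint import (
    ColorTable,
    IndexParams,
    build_index,
    build_index_from_file,
    delta_decode,
    delta_encode,
    load_index,
    read_sequences,
    save_index,
    sequence_minimizers,
)
from readtint.index_builder import (
    IndexMagicError,
    IndexTruncatedError,
    IndexVersionError,
    scan_record_offsets,
)
from readtint.synthetic_data import SimulationConfig, simulate_genome, simulate_reads, write_fasta


class TestDeltaCodec:
    def test_known_deltas(self):
        # [3,7,9] -> deltas [3,4,2], one varint byte each
        assert delta_encode([3, 7, 9]) == bytes([3, 4, 2])

    def test_empty_list_empty_payload(self):
        assert delta_encode([]) == b""
        assert delta_decode(b"").size == 0

    def test_multibyte_varint(self):
        ids = [0, 300, 10**6]
        assert delta_decode(delta_encode(ids)).tolist() == ids

    def test_rejects_unsorted(self):
        with pytest.raises(ValueError, match="increasing"):
            delta_encode([3, 3, 5])

    def test_truncated_payload_detected(self):
        payload = delta_encode([5, 10_000])
        with pytest.raises(IndexTruncatedError):
            delta_decode(payload[:-1])

    def test_roundtrip_many_random_lists(self):
        """decode∘encode == identity on 10^4 random sorted lists."""
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            n = int(rng.integers(0, 60))
            ids = np.unique(rng.integers(0, 2**31, size=n))
            assert np.array_equal(delta_decode(delta_encode(ids)), ids)

    @given(st.lists(st.integers(0, 2**32 - 1), unique=True, max_size=200))
    @settings(max_examples=100)
    def test_roundtrip_property(self, ids):
        ids = sorted(ids)
        assert delta_decode(delta_encode(ids)).tolist() == ids


class TestColorTable:
    def test_interning_is_idempotent(self):
        t = ColorTable()
        a = t.intern([0, 1])
        b = t.intern(np.asarray([0, 1], np.uint32))
        assert a == b and len(t) == 1

    def test_distinct_lists_distinct_ids(self):
        t = ColorTable()
        assert t.intern([0, 1]) != t.intern([0, 2])
        assert len(t) == 2

    def test_rejects_empty_and_unsorted(self):
        t = ColorTable()
        with pytest.raises(ValueError):
            t.intern([])
        with pytest.raises(ValueError):
            t.intern([2, 1])

    def test_table_size_equals_distinct_lists(self):
        rng = np.random.default_rng(1)
        t = ColorTable()
        seen = set()
        for _ in range(10_000):
            ids = tuple(sorted(rng.choice(20, size=rng.integers(1, 6), replace=False)))
            t.intern(list(ids))
            seen.add(ids)
        assert len(t) == len(seen)


class TestBuildIndex:
    def test_two_identical_reads_single_color(self):
        p = IndexParams(k=9, m=4, min_abundance=2, max_abundance=100,
                        filter_log2_size=16)
        seq = "ACGTACGGTACCAGTTA"
        idx = build_index([seq, seq], p, counting="exact")
        assert len(idx.colors) == 1
        assert idx.colors.color(0).tolist() == [0, 1]
        assert idx.n_minimizers == sequence_minimizers(seq, p).size

    def test_disjoint_reads_two_singleton_colors(self):
        p = IndexParams(k=4, m=4, min_abundance=1, filter_log2_size=16)
        idx = build_index(["AAAAAA", "CCCCCC"], p, counting="exact")
        assert len(idx.colors) == 2
        colors = {tuple(idx.reads_with_minimizer(mz)) for mz in idx.minimizer_map}
        assert colors == {(0,), (1,)}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_index([], IndexParams())

    def test_missing_file_error_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.fa"):
            build_index_from_file(tmp_path / "nope.fa", IndexParams())

    def test_matches_brute_force_mapping(self, small_simulation):
        """Exact-counting index == direct scan of every read's minimizers."""
        _, _, reads, _ = small_simulation
        reads = reads[:50]
        p = IndexParams(k=21, m=9, min_abundance=1, max_abundance=10**6)
        idx = build_index([r.sequence for r in reads], p, counting="exact")
        expected: dict[int, list[int]] = {}
        for r in reads:
            for mz in sequence_minimizers(r.sequence, p).tolist():
                expected.setdefault(mz, []).append(r.read_id)
        got = {
            mz: idx.reads_with_minimizer(mz).tolist() for mz in idx.minimizer_map
        }
        assert got == expected

    def test_per_read_deduplication_defines_abundance(self):
        """A minimizer repeated inside one read counts once: with
        min_abundance=2 a single read can never make it solid."""
        p = IndexParams(k=4, m=2, min_abundance=2, max_abundance=100,
                        filter_log2_size=16)
        idx = build_index(["AAAAAAAA"], p, counting="exact")
        assert idx.n_minimizers == 0
        idx2 = build_index(["AAAAAAAA", "AAAA"], p, counting="exact")
        assert idx2.n_minimizers == 1

    def test_modal_abundance_tracks_coverage(self):
        """At 10X, the most common per-read minimizer abundance is ~10."""
        config = SimulationConfig(genome_length=30_000, coverage=10,
                                  read_length_mean=3_000, read_length_spread=300,
                                  error_rate=0.0, rng_seed=3)
        genome = simulate_genome(config)
        reads, _ = simulate_reads(genome, config)
        p = IndexParams(min_abundance=1, max_abundance=10**6)
        from readtint.abundance_filter import ExactCounter

        counter = ExactCounter()
        for r in reads:
            counter.add(sequence_minimizers(r.sequence, p))
        counter._finalize()
        counts = counter._counts
        values, freq = np.unique(counts, return_counts=True)
        mode = values[np.argmax(freq)]
        assert 6 <= mode <= 14

    def test_color_count_sublinear_on_error_free_reads(self):
        """Error-free overlapping reads: distinct colors <= 2 x reads."""
        config = SimulationConfig(genome_length=20_000, coverage=8,
                                  read_length_mean=2_000, read_length_spread=200,
                                  error_rate=0.0, rng_seed=5)
        genome = simulate_genome(config)
        reads, _ = simulate_reads(genome, config)
        p = IndexParams(min_abundance=1, max_abundance=10**6)
        idx = build_index([r.sequence for r in reads], p, counting="exact")
        assert len(idx.colors) <= 2 * len(reads)

    def test_upper_abundance_bound_excludes_repeats(self):
        p = IndexParams(k=4, m=4, min_abundance=1, max_abundance=2,
                        filter_log2_size=16)
        idx = build_index(["AAAA", "AAAA", "AAAA"], p, counting="exact")
        assert idx.n_minimizers == 0


class TestSerialization:
    @pytest.fixture()
    def toy_index(self):
        p = IndexParams(k=9, m=4, min_abundance=1, max_abundance=50,
                        filter_log2_size=16)
        return build_index(["ACGTACGGTACCAGTTA", "GGTACCAGTTACGATCG"], p,
                           counting="exact")

    def test_roundtrip_equal_structures(self, toy_index, tmp_path):
        path = tmp_path / "toy.idx"
        save_index(toy_index, path)
        loaded = load_index(path)
        assert loaded.params == toy_index.params
        assert loaded.n_reads == toy_index.n_reads
        assert loaded.minimizer_map == toy_index.minimizer_map
        for cid in range(len(toy_index.colors)):
            assert np.array_equal(loaded.colors.color(cid),
                                  toy_index.colors.color(cid))

    def test_save_is_deterministic(self, toy_index, tmp_path):
        a, b = tmp_path / "a.idx", tmp_path / "b.idx"
        save_index(toy_index, a)
        save_index(toy_index, b)
        assert a.read_bytes() == b.read_bytes()

    def test_corrupted_magic_rejected(self, toy_index, tmp_path):
        path = tmp_path / "toy.idx"
        save_index(toy_index, path)
        data = bytearray(path.read_bytes())
        data[:4] = b"XXXX"
        path.write_bytes(bytes(data))
        with pytest.raises(IndexMagicError):
            load_index(path)

    def test_bad_version_rejected(self, toy_index, tmp_path):
        path = tmp_path / "toy.idx"
        save_index(toy_index, path)
        data = bytearray(path.read_bytes())
        data[4] = 99
        path.write_bytes(bytes(data))
        with pytest.raises(IndexVersionError):
            load_index(path)

    def test_truncation_rejected(self, toy_index, tmp_path):
        path = tmp_path / "toy.idx"
        save_index(toy_index, path)
        path.write_bytes(path.read_bytes()[:-5])
        with pytest.raises(IndexTruncatedError):
            load_index(path)


class TestFileInput:
    def test_fasta_roundtrip_and_offsets(self, tmp_path):
        path = tmp_path / "reads.fa"
        seqs = [("r0", "ACGTACGTAGA"), ("r1", "TTGCATGCAAC")]
        write_fasta(path, seqs)
        records = list(read_sequences(path))
        assert [r.sequence for r in records] == [s for _, s in seqs]
        assert [r.read_id for r in records] == [0, 1]
        offsets = scan_record_offsets(path)
        assert len(offsets) == 2 and offsets[0] == 0

    def test_gzip_fasta(self, tmp_path):
        import gzip

        path = tmp_path / "reads.fa.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(">a\nACGTACGTA\n>b\nTTTTGGGGA\n")
        records = list(read_sequences(path))
        assert [r.sequence for r in records] == ["ACGTACGTA", "TTTTGGGGA"]
        assert all(r.source_offset is None for r in records)

    def test_fastq(self, tmp_path):
        path = tmp_path / "reads.fq"
        path.write_text("@a\nACGT\n+\nIIII\n@b\nGGCA\n+\nIIII\n")
        assert [r.sequence for r in read_sequences(path)] == ["ACGT", "GGCA"]
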