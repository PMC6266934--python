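"""Encoding, naive hashing, rolling k-mer tables, FISH recombination."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fishash import (
    build_kmer_table,
    build_tables,
    cyclic_hash_stream,
    cyclic_naive_hash_stream,
    decompose_blocks,
    encode_sequence,
    fish_hash_stream,
    fish_multi_hash_stream,
    make_salt_table,
    naive_hash_stream,
    naive_qgram_hash,
    parse_seed,
    plan_multi,
    render_hash,
    table2_seeds,
)

from conftest import dna_sequences, seed_patterns

EXAMPLE_X = "ACTGACTGGATTGAC"
EXAMPLE_X18 = "ACTGACTGGATTGACTCC"


def _streams_equal(a, b):
    return (
        len(a) == len(b)
        and (a.hashes == b.hashes).all()
        and (a.valid == b.valid).all()
    )


class TestEncode:
    def test_acgt_mapping(self):
        enc = encode_sequence("ACGT")
        assert enc.codes.tolist() == [0, 1, 2, 3]
        assert enc.valid.all()

    def test_example_prefix_codes(self):
        enc = encode_sequence("ACGACGATTG")
        rendered = [format(c, "02b") for c in enc.codes]
        assert rendered == ["00", "01", "10", "00", "01", "10", "00", "11", "11", "10"]

    def test_ambiguous_bases_flagged_not_fatal(self):
        enc = encode_sequence("ACNGT")
        assert enc.valid.tolist() == [True, True, False, True, True]
        assert enc.codes[2] == 0

    def test_case_and_uracil_normalized(self):
        assert encode_sequence("acgu").codes.tolist() == [0, 1, 2, 3]
        assert encode_sequence("acgu").valid.all()


class TestNaive:
    def test_worked_example_positions(self, example_seed):
        enc = encode_sequence(EXAMPLE_X)
        h0, ok = naive_qgram_hash(enc, example_seed, 0)
        assert ok
        assert render_hash(h0, 10) == "10111100100100100100"
        h1, _ = naive_qgram_hash(enc, example_seed, 1)
        assert render_hash(h1, 10) == "00101111001101001101"
        # The little-endian rendering lists the last matched symbol's
        # code leftmost; the Q-gram at i=2 is TGCTGTTGAC, whose final C
        # fixes the two leading bits to 01.
        h2, _ = naive_qgram_hash(enc, example_seed, 2)
        assert render_hash(h2, 10) == "01001011111011011011"

    def test_prefix_of_weight_six(self):
        # seed truncated to its first six match offsets {0,1,3,4,5,8}:
        # the Q-gram prefix ACGACG packs to 100100100100
        seed6 = parse_seed("110111001")
        enc = encode_sequence("ACTGACTGGA")
        h, _ = naive_qgram_hash(enc, seed6, 0)
        assert render_hash(h, 6) == "100100100100"

    def test_stream_matches_per_position(self, example_seed):
        enc = encode_sequence(EXAMPLE_X)
        stream = naive_hash_stream(enc, example_seed)
        assert len(stream) == 3
        for i in range(3):
            h, ok = naive_qgram_hash(enc, example_seed, i)
            assert int(stream.hashes[i]) == h
            assert bool(stream.valid[i]) == ok

    def test_weight_one_seed_is_identity_encoding(self):
        stream = naive_hash_stream(encode_sequence("ACGT"), parse_seed("1"))
        assert stream.hashes.tolist() == [0, 1, 2, 3]

    def test_short_input_yields_empty_stream(self, example_seed):
        enc = encode_sequence("A" * (example_seed.span - 1))
        assert len(naive_hash_stream(enc, example_seed)) == 0

    def test_position_out_of_range(self, example_seed):
        enc = encode_sequence(EXAMPLE_X)
        with pytest.raises(IndexError):
            naive_qgram_hash(enc, example_seed, len(EXAMPLE_X))


class TestKmerTable:
    def test_block_hashes_of_example(self):
        enc = encode_sequence(EXAMPLE_X18)
        assert render_hash(build_kmer_table(enc, 2).hashes[0], 2) == "0100"
        assert render_hash(build_kmer_table(enc, 3).hashes[3], 3) == "010010"
        assert render_hash(build_kmer_table(enc, 5).hashes[8], 5) == "1011110010"

    def test_unit_window_equals_codes(self):
        enc = encode_sequence("ACGTNACG")
        table = build_kmer_table(enc, 1)
        assert (table.hashes == enc.codes).all()
        assert (table.valid == enc.valid).all()

    @pytest.mark.parametrize("l", [0, 20])
    def test_length_out_of_range(self, l):
        with pytest.raises(ValueError):
            build_kmer_table(encode_sequence("ACGTACGTAC"), l)

    @given(dna_sequences(min_size=1, max_size=120, with_n=True))
    def test_rolling_equals_direct_recomputation(self, seq):
        enc = encode_sequence(seq)
        for l in range(1, min(16, enc.n) + 1):
            table = build_kmer_table(enc, l)
            for i in range(enc.n - l + 1):
                direct = 0
                for j in range(l):
                    direct |= int(enc.codes[i + j]) << (2 * j)
                assert int(table.hashes[i]) == direct
                assert bool(table.valid[i]) == bool(enc.valid[i : i + l].all())
                assert direct < 4**l


class TestFish:
    def test_example_block_recombination(self, example_seed):
        enc = encode_sequence(EXAMPLE_X18)
        tables = build_tables(enc, [2, 3, 5])
        stream = fish_hash_stream(enc, example_seed, tables)
        # (0100 << 0) | (010010 << 4) | (1011110010 << 10)
        assert render_hash(stream.hashes[0], 10) == "10111100100100100100"

    def test_all_ones_seed_reduces_to_kmer_table(self):
        enc = encode_sequence(EXAMPLE_X18)
        seed = parse_seed("11111")
        tables = build_tables(enc, [5])
        stream = fish_hash_stream(enc, seed, tables)
        assert (stream.hashes == tables[5].hashes).all()

    def test_missing_table_is_an_error(self, example_seed):
        enc = encode_sequence(EXAMPLE_X18)
        with pytest.raises(KeyError, match="block length"):
            fish_hash_stream(enc, example_seed, build_tables(enc, [2, 3]))

    @given(dna_sequences(max_size=300, with_n=True), seed_patterns(max_span=45))
    def test_fish_equals_naive_oracle(self, seq, pattern):
        seed = parse_seed(pattern)
        enc = encode_sequence(seq)
        lengths = set(decompose_blocks(seed).lengths)
        tables = build_tables(enc, [l for l in lengths if l <= enc.n])
        fish = fish_hash_stream(enc, seed, tables) if enc.n >= seed.span else None
        naive = naive_hash_stream(enc, seed)
        if fish is None:
            assert len(naive) == 0
        else:
            assert _streams_equal(fish, naive)
            ok = naive.hashes[naive.valid]
            if len(ok):
                assert int(ok.max()) < 4**seed.weight

    def test_validity_propagates_to_covering_windows_only(self, example_seed):
        # flip x[8] (a matched offset for i=0 via 8+0, i=3 via 5+3, ...)
        base = "ACTGACTGGATTGACTCC"
        flipped = base[:8] + "N" + base[9:]
        enc = encode_sequence(flipped)
        naive = naive_hash_stream(enc, example_seed)
        for i in range(len(naive)):
            covered = (8 - i) in example_seed.shape
            assert bool(naive.valid[i]) == (not covered)
        tables = build_tables(enc, [2, 3, 5])
        assert _streams_equal(naive, fish_hash_stream(enc, example_seed, tables))


class TestMultiSeed:
    def test_multi_matches_single_seed_runs(self):
        seeds = table2_seeds()
        plan = plan_multi(seeds)
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGTN"), size=150, p=[0.24] * 4 + [0.04]))
        enc = encode_sequence(seq)
        streams = fish_multi_hash_stream(enc, plan)
        assert len(streams) == 9
        for seed, stream in zip(seeds, streams):
            tables = build_tables(enc, set(decompose_blocks(seed).lengths))
            assert _streams_equal(stream, fish_hash_stream(enc, seed, tables))

    def test_tables_built_once_per_union_length(self, monkeypatch):
        import fishash.hashcore as hc

        calls = []
        original = hc.build_kmer_table

        def counting(enc, l):
            calls.append(l)
            return original(enc, l)

        monkeypatch.setattr(hc, "build_kmer_table", counting)
        seeds = [parse_seed("1101110011111"), parse_seed("110111")]
        plan = plan_multi(seeds)
        fish_multi_hash_stream(encode_sequence("ACGT" * 20), plan)
        assert sorted(calls) == [2, 3, 5]

    def test_singleton_plan_degenerates_to_single_seed(self, example_seed):
        enc = encode_sequence(EXAMPLE_X18)
        [stream] = fish_multi_hash_stream(enc, plan_multi([example_seed]))
        tables = build_tables(enc, [2, 3, 5])
        assert _streams_equal(stream, fish_hash_stream(enc, example_seed, tables))

    def test_reads_shorter_than_span_give_empty_streams(self):
        seeds = [parse_seed("1" * 31), parse_seed("11")]
        streams = fish_multi_hash_stream(encode_sequence("ACGTACGT"), plan_multi(seeds))
        assert len(streams[0]) == 0
        assert len(streams[1]) == 7


class TestCyclicVariant:
    def test_weight_one_seed_returns_salt_words(self):
        salt = make_salt_table(3)
        enc = encode_sequence("ACGT")
        stream = cyclic_naive_hash_stream(enc, parse_seed("1"), salt)
        assert (stream.hashes == salt).all()

    @given(dna_sequences(max_size=200, with_n=True), seed_patterns(max_span=40))
    def test_block_recombination_equals_naive(self, seq, pattern):
        seed = parse_seed(pattern)
        enc = encode_sequence(seq)
        salt = make_salt_table(12345)
        naive = cyclic_naive_hash_stream(enc, seed, salt)
        fish = cyclic_hash_stream(enc, seed, salt)
        assert _streams_equal(naive, fish)

    def test_distinct_salts_give_distinct_streams(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        enc = encode_sequence(seq)
        seed = parse_seed("1101110011111")
        a = cyclic_naive_hash_stream(enc, seed, make_salt_table(1))
        b = cyclic_naive_hash_stream(enc, seed, make_salt_table(2))
        assert (a.hashes != b.hashes).any()

    def test_malformed_salt_rejected(self):
        with pytest.raises(ValueError, match="salt"):
            cyclic_naive_hash_stream(
                encode_sequence("ACGT"), parse_seed("1"), np.zeros(3, dtype=np.uint64)
            )
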