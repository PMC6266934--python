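"""Spaced-seed hashing: naive per-position oracle and FISH block indexing.

The hash of a Q-gram packs the 2-bit codes of its ``W`` matched symbols
(A=00, C=01, G=10, T=11) into one unsigned integer.  The symbol at seed
offset ``k`` lands at bit offset ``2*m(k)``, where ``m(k)`` counts the
match positions left of ``k`` — so the first matched symbol occupies the
least-significant bits:

    h(x[i+Q]) = OR over k in Q of  code(x[i+k]) << 2*m(k)

The naive route evaluates this sum symbol by symbol at every position
and serves as the correctness oracle.  FISH instead builds, for each
distinct unit-block length ``l`` of the seed, a table of the hashes of
all contiguous l-mers (computed left to right with a constant-time
rolling update), then assembles each Q-gram hash by OR-ing the shifted
block hashes looked up in those tables.  Both routes are bitwise
identical wherever the window contains only A/C/G/T.

Non-ACGT symbols (N and friends) are encoded as 0 and flagged invalid;
validity propagates through every window and stream so callers can mask
positions whose Q-gram touched an ambiguous base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .seedspec import MultiSeedPlan, SpacedSeed, decompose_blocks

__all__ = [
    "EncodedSequence",
    "KmerTable",
    "HashStream",
    "encode_sequence",
    "naive_qgram_hash",
    "naive_hash_stream",
    "build_kmer_table",
    "build_tables",
    "fish_hash_stream",
    "fish_multi_hash_stream",
    "make_salt_table",
    "cyclic_naive_hash_stream",
    "cyclic_hash_stream",
    "render_hash",
]

_U64 = np.uint64
_MASK64 = _U64(0xFFFFFFFFFFFFFFFF)

# 256-entry lookup tables: code and validity per raw byte.  Lower case is
# normalized and U maps to T; everything else is code 0, invalid.
_CODE_LUT = np.zeros(256, dtype=np.uint8)
_VALID_LUT = np.zeros(256, dtype=bool)
for _sym, _code in (("A", 0), ("C", 1), ("G", 2), ("T", 3), ("U", 3)):
    for _b in (ord(_sym), ord(_sym.lower())):
        _CODE_LUT[_b] = _code
        _VALID_LUT[_b] = True


@dataclass(frozen=True)
class EncodedSequence:
    """2-bit encoded DNA with per-symbol validity flags."""

    codes: np.ndarray  # uint8, values in {0,1,2,3}
    valid: np.ndarray  # bool, parallel to codes

    @property
    def n(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class KmerTable:
    """Hashes of every contiguous l-mer of a sequence.

    ``hashes[i]`` packs the codes of ``x[i .. i+l-1]`` with symbol 0 in
    the least-significant bits; ``valid[i]`` is true iff the whole
    window is A/C/G/T.
    """

    l: int
    hashes: np.ndarray  # uint64, length n - l + 1
    valid: np.ndarray


@dataclass(frozen=True)
class HashStream:
    """Ordered Q-gram hashes h(x[i+Q]) for i = 0 .. n - span."""

    seed: SpacedSeed
    hashes: np.ndarray  # uint64, length max(0, n - span + 1)
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.hashes)


def encode_sequence(raw: str) -> EncodedSequence:
    """Encode a text sequence into 2-bit codes plus validity flags.

    Case-insensitive; ``U`` is treated as ``T``.  Any other symbol gets
    code 0 and ``valid=False`` — degenerate input is flagged, never
    fatal.
    """
    data = np.frombuffer(raw.encode("latin-1", errors="replace"), dtype=np.uint8)
    return EncodedSequence(codes=_CODE_LUT[data], valid=_VALID_LUT[data])


def render_hash(value: int, weight: int) -> str:
    """Binary rendering of a packed hash, zero-padded to ``2*weight`` bits.

    The plain big-endian binary string of the integer: the last matched
    symbol's code appears leftmost, the first matched symbol's
    rightmost.
    """
    return format(int(value), f"0{2 * weight}b")


def naive_qgram_hash(
    enc: EncodedSequence, seed: SpacedSeed, i: int
) -> tuple[int, bool]:
    """Hash the single Q-gram at position ``i`` symbol by symbol.

    Returns ``(hash, valid)``; the Python-int reference computation that
    all fast paths are checked against.
    """
    if not 0 <= i <= enc.n - seed.span:
        raise IndexError(
            f"position {i} out of range for n={enc.n}, span={seed.span}"
        )
    h = 0
    ok = True
    for k in seed.shape:
        h |= int(enc.codes[i + k]) << (2 * seed.m(k))
        ok &= bool(enc.valid[i + k])
    return h, ok


def naive_hash_stream(enc: EncodedSequence, seed: SpacedSeed) -> HashStream:
    """Hash every Q-gram by direct evaluation at each position.

    Each symbol under a match position is re-read and re-encoded for
    every window it appears in, which is exactly the per-position cost
    FISH avoids; the arithmetic is vectorized over positions but the
    per-symbol structure is unchanged.
    """
    length = enc.n - seed.span + 1
    if length <= 0:
        return _empty_stream(seed)
    hashes = np.zeros(length, dtype=_U64)
    valid = np.ones(length, dtype=bool)
    codes = enc.codes.astype(_U64)
    for k in seed.shape:
        hashes |= codes[k : k + length] << _U64(2 * seed.m(k))
        valid &= enc.valid[k : k + length]
    return HashStream(seed=seed, hashes=hashes, valid=valid)


def _roll_kmers(codes: np.ndarray, l: int) -> np.ndarray:
    """Rolling scan: pack the first window, then slide in constant time.

    hashes[i+1] = (hashes[i] >> 2) | (code[i+l] << 2*(l-1))
    """
    length = codes.shape[0] - l + 1
    out = np.empty(length, dtype=np.uint64)
    h = np.uint64(0)
    for j in range(l):
        h |= np.uint64(codes[j]) << np.uint64(2 * j)
    out[0] = h
    top = np.uint64(2 * (l - 1))
    two = np.uint64(2)
    for i in range(length - 1):
        h = (h >> two) | (np.uint64(codes[i + l]) << top)
        out[i + 1] = h
    return out


try:  # compile the inner scan when numba is present; same code either way
    from numba import njit as _njit

    _roll_kmers = _njit(cache=False, nogil=True)(_roll_kmers)
except ImportError:  # pragma: no cover - interpreter fallback
    pass


def build_kmer_table(enc: EncodedSequence, l: int) -> KmerTable:
    """Build the rolling table of all contiguous l-mer hashes.

    The first window is packed symbol by symbol; every subsequent window
    reuses the ``l-1`` overlapping symbols in constant time.

    Raises ``ValueError`` when ``l`` is not in ``1..n``.
    """
    n = enc.n
    if l < 1 or l > n:
        raise ValueError(f"block length {l} outside 1..{n}")
    out = _roll_kmers(enc.codes, l)
    length = n - l + 1

    # window validity: no invalid symbol inside [i, i+l-1]
    bad = np.flatnonzero(~enc.valid)
    valid = np.ones(length, dtype=bool)
    for b in bad:
        lo = max(0, b - l + 1)
        hi = min(length - 1, b)
        if lo <= hi:
            valid[lo : hi + 1] = False
    return KmerTable(l=l, hashes=out, valid=valid)


def build_tables(enc: EncodedSequence, lengths: Sequence[int]) -> dict[int, KmerTable]:
    """Build one k-mer table per distinct length, each exactly once."""
    return {l: build_kmer_table(enc, l) for l in dict.fromkeys(lengths)}


def fish_hash_stream(
    enc: EncodedSequence,
    seed: SpacedSeed,
    tables: Mapping[int, KmerTable],
) -> HashStream:
    """Assemble Q-gram hashes from pre-built block tables.

    For each unit block starting at ``b`` with length ``l`` the block
    hash is ``tables[l].hashes[i + b]``, shifted left by ``2*m(b)`` and
    OR-ed into the result.  Bitwise identical to the naive stream at
    every valid position.

    Raises ``KeyError`` when a required block length has no table.
    """
    length = enc.n - seed.span + 1
    if length <= 0:
        return _empty_stream(seed)
    blocks = decompose_blocks(seed)
    missing = sorted(set(blocks.lengths) - set(tables))
    if missing:
        raise KeyError(f"no k-mer table for block length(s) {missing}")
    hashes = np.zeros(length, dtype=_U64)
    valid = np.ones(length, dtype=bool)
    for b, l in blocks:
        t = tables[l]
        hashes |= t.hashes[b : b + length] << _U64(2 * seed.m(b))
        valid &= t.valid[b : b + length]
    return HashStream(seed=seed, hashes=hashes, valid=valid)


def fish_multi_hash_stream(
    enc: EncodedSequence, plan: MultiSeedPlan
) -> list[HashStream]:
    """Hash one sequence under several seeds with shared block tables.

    Exactly ``len(plan.union_lengths)`` tables are built (via
    ``build_tables``); seeds sharing a block length share the table.
    Output stream ``s`` equals ``fish_hash_stream`` for seed ``s``.
    """
    usable = [l for l in plan.union_lengths if l <= enc.n]
    tables = build_tables(enc, usable) if enc.n >= min(
        (s.span for s in plan.seeds), default=0
    ) else {}
    streams: list[HashStream] = []
    for seed, recipe in zip(plan.seeds, plan.recipes):
        length = enc.n - seed.span + 1
        if length <= 0:
            streams.append(_empty_stream(seed))
            continue
        hashes = np.zeros(length, dtype=_U64)
        valid = np.ones(length, dtype=bool)
        for b, l, shift in recipe:
            t = tables[l]
            hashes |= t.hashes[b : b + length] << _U64(shift)
            valid &= t.valid[b : b + length]
        streams.append(HashStream(seed=seed, hashes=hashes, valid=valid))
    return streams


def _empty_stream(seed: SpacedSeed) -> HashStream:
    return HashStream(
        seed=seed,
        hashes=np.empty(0, dtype=_U64),
        valid=np.empty(0, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Cyclic-polynomial (buzhash) variant: rotations for shifts, XOR for OR,
# and a random 64-bit word per nucleotide instead of the 2-bit code.
# ---------------------------------------------------------------------------


def make_salt_table(rng_seed: int) -> np.ndarray:
    """Four random 64-bit words, one per nucleotide, from a stated seed."""
    rng = np.random.default_rng(rng_seed)
    return rng.integers(0, 2**64, size=4, dtype=_U64)


def _rotl(values: np.ndarray, r: int) -> np.ndarray:
    r %= 64
    if r == 0:
        return values.copy()
    return (values << _U64(r)) | (values >> _U64(64 - r))


def _check_salt(salt_table: np.ndarray) -> np.ndarray:
    salt = np.asarray(salt_table, dtype=_U64)
    if salt.shape != (4,):
        raise ValueError("salt table must hold exactly 4 64-bit words")
    return salt


def cyclic_naive_hash_stream(
    enc: EncodedSequence, seed: SpacedSeed, salt_table: np.ndarray
) -> HashStream:
    """Per-position cyclic-polynomial oracle.

    stream[i] = XOR over k in Q of rotl64(salt[x[i+k]], m(k) mod 64).
    """
    salt = _check_salt(salt_table)
    length = enc.n - seed.span + 1
    if length <= 0:
        return _empty_stream(seed)
    salted = salt[enc.codes]
    hashes = np.zeros(length, dtype=_U64)
    valid = np.ones(length, dtype=bool)
    for k in seed.shape:
        hashes ^= _rotl(salted[k : k + length], seed.m(k))
        valid &= enc.valid[k : k + length]
    return HashStream(seed=seed, hashes=hashes, valid=valid)


def _cyclic_block_table(enc: EncodedSequence, l: int, salt: np.ndarray) -> np.ndarray:
    """Rolling buzhash of every l-mer; symbol j rotated by its in-block index.

    Sliding by one symbol: drop the outgoing word, rotate the remainder
    right by one, and XOR in the incoming word at rotation ``l-1``.
    """
    n = enc.n
    if l < 1 or l > n:
        raise ValueError(f"block length {l} outside 1..{n}")
    salted = salt[enc.codes]
    length = n - l + 1
    out = np.empty(length, dtype=_U64)
    h = _U64(0)
    for j in range(l):
        h ^= _rotl(salted[j : j + 1], j)[0]
    out[0] = h
    for i in range(length - 1):
        h ^= salted[i]
        h = (h >> _U64(1)) | ((h & _U64(1)) << _U64(63))
        h ^= _rotl(salted[i + l : i + l + 1], l - 1)[0]
        out[i + 1] = h
    return out


def cyclic_hash_stream(
    enc: EncodedSequence,
    seed: SpacedSeed,
    salt_table: np.ndarray,
) -> HashStream:
    """FISH recombination of the cyclic-polynomial hash.

    Block hashes (rotation amount = within-block index) are looked up in
    per-length rolling tables, rotated left by ``m(block start) mod 64``
    and XOR-ed; elementwise equal to ``cyclic_naive_hash_stream``.
    """
    salt = _check_salt(salt_table)
    length = enc.n - seed.span + 1
    if length <= 0:
        return _empty_stream(seed)
    blocks = decompose_blocks(seed)
    tables = {l: _cyclic_block_table(enc, l, salt) for l in set(blocks.lengths)}
    hashes = np.zeros(length, dtype=_U64)
    valid = np.ones(length, dtype=bool)
    for b, l in blocks:
        hashes ^= _rotl(tables[l][b : b + length], seed.m(b))
        for j in range(l):
            valid &= enc.valid[b + j : b + j + length]
    return HashStream(seed=seed, hashes=hashes, valid=valid)
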