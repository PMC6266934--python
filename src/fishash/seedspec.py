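"""Spaced-seed parsing, validation, and block decomposition.

A spaced seed is a binary pattern over {0,1} where a ``1`` demands a
symbol match and a ``0`` is a don't-care.  It is fully described by its
*shape* ``Q`` (the 0-based offsets of the 1s), its *weight* ``W = |Q|``
and its *span* ``max(Q) + 1``.  For hashing, a seed is decomposed into
its *unit blocks*: the maximal runs of consecutive 1s.  Each block of
length ``l`` is a contiguous l-mer, so its hash can be looked up in a
rolling l-mer table instead of being recomputed symbol by symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "SeedError",
    "SpacedSeed",
    "BlockDecomposition",
    "MultiSeedPlan",
    "parse_seed",
    "decompose_blocks",
    "plan_multi",
    "load_seed_file",
]

#: Largest supported weight: at 2 bits per matched symbol the hash of a
#: weight-32 seed fills a 64-bit word exactly.
MAX_WEIGHT = 32


class SeedError(ValueError):
    """A seed pattern violates the spaced-seed grammar."""


@dataclass(frozen=True)
class SpacedSeed:
    """A validated spaced seed.

    Attributes
    ----------
    pattern:
        The binary string, e.g. ``"1101110011111"``.
    shape:
        Sorted tuple of 0-based offsets of the 1s (the shape ``Q``).
    weight:
        Number of match positions, ``|Q|``.
    span:
        Total length of the pattern, ``max(Q) + 1``.
    prefix_weight:
        Tuple ``m`` of length ``span`` where ``m[k]`` counts the 1s
        strictly left of offset ``k``; ``2*m[k]`` is the bit offset of
        symbol ``k``'s code inside the packed hash.
    """

    pattern: str
    shape: tuple[int, ...]
    weight: int
    span: int
    prefix_weight: tuple[int, ...] = field(repr=False)

    def m(self, k: int) -> int:
        """Number of match positions strictly left of offset ``k``."""
        return self.prefix_weight[k]

    def render(self) -> str:
        """Reconstruct the pattern string from the shape."""
        chars = ["0"] * self.span
        for k in self.shape:
            chars[k] = "1"
        return "".join(chars)


@dataclass(frozen=True)
class BlockDecomposition:
    """Unit blocks of a seed: parallel lists of start offsets and lengths."""

    starts: tuple[int, ...]
    lengths: tuple[int, ...]

    def __iter__(self):
        return iter(zip(self.starts, self.lengths))


@dataclass(frozen=True)
class MultiSeedPlan:
    """Shared-table execution plan for several seeds.

    ``union_lengths`` lists every distinct unit-block length across the
    seeds; one rolling k-mer table per entry suffices for all of them.
    ``recipes[s]`` holds ``(block_start, block_length, bit_shift)``
    triples for seed ``s``, with ``bit_shift = 2 * m(block_start)``.
    """

    seeds: tuple[SpacedSeed, ...]
    union_lengths: tuple[int, ...]
    recipes: tuple[tuple[tuple[int, int, int], ...], ...]


def parse_seed(pattern: str) -> SpacedSeed:
    """Parse and validate a spaced-seed pattern.

    Parameters
    ----------
    pattern:
        Non-empty string over ``{0,1}`` that starts and ends with ``1``.
        An all-1 pattern (a contiguous k-mer) is accepted as a
        degenerate seed with a single unit block.

    Raises
    ------
    SeedError
        If the pattern is empty, contains characters outside ``{0,1}``,
        starts or ends with ``0``, or has weight above 32 (the hash of a
        heavier seed would overflow a 64-bit word).
    """
    if not pattern:
        raise SeedError("seed pattern is empty")
    bad = set(pattern) - {"0", "1"}
    if bad:
        raise SeedError(
            f"seed pattern contains characters outside {{0,1}}: {sorted(bad)!r}"
        )
    if pattern[0] != "1":
        raise SeedError("seed pattern must start with '1'")
    if pattern[-1] != "1":
        raise SeedError("seed pattern must end with '1'")

    shape = tuple(k for k, c in enumerate(pattern) if c == "1")
    weight = len(shape)
    if weight > MAX_WEIGHT:
        raise SeedError(
            f"seed weight {weight} exceeds the supported maximum of "
            f"{MAX_WEIGHT} (hash no longer fits a 64-bit word)"
        )
    span = len(pattern)

    m = [0] * span
    count = 0
    for k in range(span):
        m[k] = count
        if pattern[k] == "1":
            count += 1

    return SpacedSeed(
        pattern=pattern,
        shape=shape,
        weight=weight,
        span=span,
        prefix_weight=tuple(m),
    )


def decompose_blocks(seed: SpacedSeed) -> BlockDecomposition:
    """Split a seed into its maximal runs of consecutive 1s.

    Returns the block start offsets ``B`` and lengths ``B_L`` in
    left-to-right order.  The blocks tile the shape exactly: expanding
    each block back into 1s (with 0s elsewhere) reproduces the pattern.
    """
    starts: list[int] = []
    lengths: list[int] = []
    prev = None
    for k in seed.shape:
        if prev is None or k - prev > 1:
            starts.append(k)
            lengths.append(1)
        else:
            lengths[-1] += 1
        prev = k
    return BlockDecomposition(starts=tuple(starts), lengths=tuple(lengths))


def plan_multi(seeds: Sequence[SpacedSeed]) -> MultiSeedPlan:
    """Build a shared-table plan for a set of seeds.

    Seeds that share a unit-block length reuse the same k-mer table, so
    only ``|union of block lengths|`` tables are ever built.

    Raises
    ------
    SeedError
        On an empty seed list.
    """
    if not seeds:
        raise SeedError("at least one seed is required")
    lengths: set[int] = set()
    recipes: list[tuple[tuple[int, int, int], ...]] = []
    for seed in seeds:
        blocks = decompose_blocks(seed)
        lengths.update(blocks.lengths)
        recipes.append(
            tuple((b, l, 2 * seed.m(b)) for b, l in blocks)
        )
    return MultiSeedPlan(
        seeds=tuple(seeds),
        union_lengths=tuple(sorted(lengths)),
        recipes=tuple(recipes),
    )


def load_seed_file(path) -> list[SpacedSeed]:
    """Read seed patterns from a text file, one per line.

    Blank lines are skipped; ``#`` starts a comment (full-line or
    trailing).
    """
    seeds: list[SpacedSeed] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            try:
                seeds.append(parse_seed(text))
            except SeedError as exc:
                raise SeedError(f"{path}:{lineno}: {exc}") from exc
    return seeds
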