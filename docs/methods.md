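# Methods

## The problem

Spaced seeds generalize contiguous k-mers: a binary pattern such as
`1101110011111` declares which offsets of a window must match (`1`) and
which are don't-cares (`0`). Seed-based sequence comparison —
metagenomic read classification in particular — needs, for every
position `i` of every read, the hash of the *Q-gram* `x[i+Q]`: the
string of the `W` symbols under the seed's match offsets
`Q = {k : pattern[k] = '1'}`.

With the 2-bit nucleotide code (`A=00, C=01, G=10, T=11`) the hash is
the Rabin–Karp packing

    h(x[i+Q]) = OR over k in Q of  code(x[i+k]) << 2*m(k)

where `m(k)` counts the match offsets strictly left of `k`. The first
matched symbol occupies the least-significant bit pair, so the plain
big-endian binary rendering of the integer lists the *last* matched
symbol's code leftmost. All stored hashes use this layout; `W <= 32`
keeps every hash inside one 64-bit word (heavier seeds are rejected at
parse time rather than silently overflowing).

Evaluating the formula directly reads and encodes every symbol `W`
times over the course of a scan. That per-position route is kept as the
package's correctness oracle (`naive_hash_stream`), and is the baseline
the benchmark harness compares against.

## Block indexing

The fast route decomposes the seed into its *unit blocks* — maximal
runs of consecutive 1s. For `1101110011111` the blocks start at
`B = {0, 3, 8}` with lengths `B_L = {2, 3, 5}`. A block of length `l`
covers `l` contiguous symbols, so its contribution at position `i+b` is
exactly the hash of a plain l-mer. For each distinct `l` in `B_L` the
scan first builds a table `T_l` of the hashes of all `n-l+1` contiguous
l-mers using the constant-time rolling update

    T_l[i+1] = (T_l[i] >> 2) | (code(x[i+l]) << 2*(l-1))

(first window packed symbol by symbol, single left-to-right pass). The
Q-gram hash is then assembled per position by OR-ing the shifted block
hashes `T_l[i+b] << 2*m(b)` — each symbol is encoded once per distinct
block length it sits under, instead of once per match offset.

With several seeds the tables are shared: one table per length in the
*union* of the seeds' block lengths serves all of them. The nine
benchmark seeds (weight 22, span 31) jointly need only 7 tables where
per-seed runs would build 41.

Streams and tables are built per input read, so memory stays
proportional to the longest read, matching the intended per-read
scanning of sequencing datasets.

## Ambiguous bases

Non-ACGT symbols (`N` etc.) are encoded as code 0 and flagged invalid;
every k-mer table entry and stream position carries a validity flag
that is the AND of its window's symbol flags. A stream position is
valid iff all `W` matched symbols are A/C/G/T — don't-care positions
never affect validity. Hashes at invalid positions are still computed
(from the 0-codes) and written with `valid=0`, never replaced by a
sentinel, so output shapes are independent of input content. Input is
uppercased and `U` is treated as `T`.

## Cyclic-polynomial variant

The same block recombination works for the cyclic polynomial (buzhash)
family: replace the 2-bit code with a table of four random 64-bit words
(derived from a caller-supplied RNG seed), shifts with left-rotations
by `m(k) mod 64`, and OR with XOR. Block tables use the within-block
index as the rotation amount and roll via
`h' = rotr(h XOR salt(out), 1) XOR rotl(salt(in), l-1)`; recombination
rotates each block hash by `m(b) mod 64`. The naive and block-indexed
forms agree elementwise and are property-tested against each other.

## Synthetic reads

The generator emits uniform random A/C/G/T reads with configurable
count, length, GC content (G and C equiprobable at `gc/2`, likewise
A/T), and a per-base probability of replacement by `N`. Defaults are
1000 reads of 100 bp, GC 0.5, no Ns — a typical short-read setting;
tests sweep lengths across roughly 80–700 bp to cover the short- and
long-read regimes of public benchmark datasets. Sequencing-error
profiles are deliberately not emulated: a substituted base is just
another base to a hash function, so uniform reads exercise every code
path the hasher has. Consequently, passing tests demonstrate hashing
correctness and table sharing, not anything about classification
accuracy on real communities. Randomness comes from numpy's PCG64
generator, which is reproducible across platforms for a fixed seed.

## Numerical and design choices

- **Bit layout.** Any consistent layout yields isomorphic hash streams;
  the one fixed here (first matched symbol least significant) is chosen
  because its binary rendering matches the little-endian display
  convention used in the worked examples, leading zeros included.
- **Degenerate seeds.** All-1 patterns (`W == span`) are accepted: block
  indexing then reduces to a single k-mer table lookup, a useful
  boundary case. Empty patterns, non-binary characters, and patterns
  starting/ending in `0` are rejected with errors naming the property.
- **Offsets** are 0-based everywhere, including TSV output.
- **Reads shorter than the span** yield empty streams (length
  `max(0, n - span + 1)`), never an error; the multi-seed path skips
  building tables longer than the read.
- **Rolling kernel.** The per-table scan is a sequential recurrence; it
  is compiled with numba when that package is importable and otherwise
  runs as the identical interpreted loop. Results are bit-identical
  either way.
- **Benchmark harness.** All three methods (naive, block-indexed,
  shared-table) are cross-verified bitwise on the full input before any
  timing is taken; a mismatch aborts the run as a correctness bug.
  Reported seconds are medians over the requested repetitions. Timings
  are informational only — wall-clock speedups depend on hardware and
  implementation — so the asserted properties are output equality and
  that the shared-table planner never builds more tables than the sum
  of per-seed runs.
- **Problem sizes in tests.** The oracle-equivalence property is
  checked on 1000 random read/seed pairs (read lengths 80–700, seed
  spans up to 45, weights up to 32, match densities 0.3–1.0), chosen to
  cover the span/weight envelope of published seed sets while keeping
  the default suite fast.

## Known limitations

- Hash width is one 64-bit word; seeds of weight above 32 are rejected
  rather than hashed with multi-word arithmetic.
- No canonical (strand-symmetric) hashing, minimizers, or downstream
  counting/indexing of the hash streams.
- Seed design (sensitivity or overlap-complexity optimization) is out
  of scope; seeds are inputs.
- The binary container assumes every record is hashed with the same
  seed list (the header stores one seed set).
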