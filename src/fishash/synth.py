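"""Reproducible synthetic reads and the benchmark seed fixtures.

The generator emits uniform random A/C/G/T reads (optionally with a
configurable GC content and a per-base probability of an ambiguous
``N``).  Sequencing-error profiles are deliberately not emulated: a
substituted base is just another base to a hash function, so uniform
random reads exercise the hashing machinery fully.  Randomness comes
from numpy's PCG64 generator, which is deterministic for a fixed seed
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterator

import numpy as np

from .seedspec import SpacedSeed, parse_seed
from .seqio import SequenceRecord

__all__ = [
    "SimulationConfig",
    "simulate_reads",
    "write_reads",
    "table2_seeds",
]

_ALPHABET = np.frombuffer(b"ACGTN", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic read set.

    ``read_length`` defaults to 100 bp, a typical short-read length;
    the benchmark datasets span roughly 80–700 bp.  ``gc_content`` is
    the expected G+C fraction (G and C equiprobable, likewise A and T).
    ``n_rate`` is the per-base probability of replacement by ``N``.
    """

    n_reads: int = 1000
    read_length: int = 100
    rng_seed: int = 0
    gc_content: float = 0.5
    n_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length < 0:
            raise ValueError("read_length must be >= 0")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.n_rate <= 1.0:
            raise ValueError("n_rate must be in [0, 1]")


def simulate_reads(config: SimulationConfig) -> Iterator[SequenceRecord]:
    """Yield ``n_reads`` random reads, deterministic for a fixed seed.

    Base probabilities are ``(1-gc)/2`` each for A/T and ``gc/2`` each
    for G/C; each base is then independently replaced by ``N`` with
    probability ``n_rate``.  Read ids are ``read_0, read_1, ...``.
    """
    rng = np.random.default_rng(config.rng_seed)
    at = (1.0 - config.gc_content) / 2.0
    gc = config.gc_content / 2.0
    probs = np.array([at, gc, gc, at])
    for i in range(config.n_reads):
        codes = rng.choice(4, size=config.read_length, p=probs)
        if config.n_rate > 0.0:
            mask = rng.random(config.read_length) < config.n_rate
            codes = np.where(mask, 4, codes)
        seq = _ALPHABET[codes].tobytes().decode("ascii")
        yield SequenceRecord(id=f"read_{i}", sequence=seq)


def write_reads(config: SimulationConfig, path, format: str = "fasta") -> int:
    """Write a simulated read set to FASTA or FASTQ; returns read count.

    FASTQ records get the constant quality character ``I`` for every
    base.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    count = 0
    with open(path, "w") as fh:
        for rec in simulate_reads(config):
            if format == "fasta":
                fh.write(f">{rec.id}\n{rec.sequence}\n")
            else:
                fh.write(
                    f"@{rec.id}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n"
                )
            count += 1
    return count


def table2_seeds() -> list[SpacedSeed]:
    """The nine weight-22, span-31 spaced seeds used in the benchmarks.

    Three seeds per design family (hit probability, overlap complexity,
    sensitivity), shipped as a packaged text fixture.
    """
    text = (
        resources.files("fishash").joinpath("data/experiment_seeds.txt").read_text()
    )
    seeds = []
    for line in text.splitlines():
        pattern = line.split("#", 1)[0].strip()
        if pattern:
            seeds.append(parse_seed(pattern))
    return seeds
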