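"""Sequence input and hash-stream output.

FASTA/FASTQ parsing is delegated to Biopython's ``SeqIO``; gzip input is
transparent by file extension.  Hash streams go out either as TSV (one
line per record/seed/position — greppable and diffable) or as a compact
self-describing binary container of little-endian 64-bit words.
"""

from __future__ import annotations

import gzip
import io
import json
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .hashcore import HashStream

__all__ = [
    "SequenceRecord",
    "read_sequences",
    "write_hash_streams",
    "read_hash_streams_binary",
    "TSV_HEADER",
]

TSV_HEADER = "record_id\tseed_index\tposition\thash\tvalid"

_BINARY_MAGIC = b"FISHB"
_BINARY_VERSION = 1


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (uppercase-normalized text)."""

    id: str
    sequence: str


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _detect_format(path) -> str:
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(
        f"{path}: cannot auto-detect format (first character {first!r}, "
        "expected '>' for FASTA or '@' for FASTQ)"
    )


def read_sequences(path, format: str = "auto") -> Iterator[SequenceRecord]:
    """Yield records from a FASTA/FASTQ file in file order.

    ``format='auto'`` sniffs the first character; ``.gz`` paths are
    decompressed on the fly.  FASTQ quality lines are parsed and
    discarded.  A malformed record raises ``ValueError`` naming its
    0-based index.
    """
    if format == "auto":
        format = _detect_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    with _open_text(path) as fh:
        parser = SeqIO.parse(fh, format)
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"{path}: malformed record {index}: {exc}") from exc
            yield SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())
            index += 1


def write_hash_streams(
    per_record: Iterable[tuple[str, Sequence[HashStream]]],
    path,
    mode: str = "tsv",
) -> dict[str, int]:
    """Write hash streams for many records and seeds.

    Parameters
    ----------
    per_record:
        Iterable of ``(record_id, [stream for each seed])``.
    mode:
        ``'tsv'`` — header line then one ``record_id, seed_index,
        position, hash (unsigned decimal), valid (0/1)`` line per
        position.  Invalid positions keep their computed hash and carry
        ``valid=0``; no sentinel values.
        ``'binary'`` — magic + JSON header (seed patterns, record ids
        and lengths) followed by raw little-endian uint64 hash words and
        packed validity bits per (record, seed) stream.

    Returns summary counts: records, streams, positions written.
    """
    if mode == "tsv":
        return _write_tsv(per_record, path)
    if mode == "binary":
        return _write_binary(per_record, path)
    raise ValueError(f"unsupported output mode {mode!r}")


def _write_tsv(per_record, path) -> dict[str, int]:
    records = streams = positions = 0
    with open(path, "w") as fh:
        fh.write(TSV_HEADER + "\n")
        for record_id, seed_streams in per_record:
            records += 1
            for seed_index, stream in enumerate(seed_streams):
                streams += 1
                valid = stream.valid
                for pos, h in enumerate(stream.hashes):
                    fh.write(
                        f"{record_id}\t{seed_index}\t{pos}\t{int(h)}\t"
                        f"{int(valid[pos])}\n"
                    )
                positions += len(stream)
    return {"records": records, "streams": streams, "positions": positions}


def _write_binary(per_record, path) -> dict[str, int]:
    # Materialize so the header can state counts up front.
    entries = [(rid, list(streams)) for rid, streams in per_record]
    seeds: list[str] = []
    if entries:
        seeds = [s.seed.pattern for s in entries[0][1]]
    header = {
        "version": _BINARY_VERSION,
        "seeds": seeds,
        "records": [
            {"id": rid, "lengths": [len(s) for s in streams]}
            for rid, streams in entries
        ],
    }
    blob = json.dumps(header).encode()
    positions = 0
    with open(path, "wb") as fh:
        fh.write(_BINARY_MAGIC)
        fh.write(struct.pack("<I", len(blob)))
        fh.write(blob)
        for _, streams in entries:
            for stream in streams:
                fh.write(stream.hashes.astype("<u8").tobytes())
                fh.write(np.packbits(stream.valid).tobytes())
                positions += len(stream)
    return {
        "records": len(entries),
        "streams": sum(len(s) for _, s in entries),
        "positions": positions,
    }


def read_hash_streams_binary(path) -> list[tuple[str, list[tuple[np.ndarray, np.ndarray]]]]:
    """Read back a binary container; inverse of the binary writer.

    Returns ``(record_id, [(hashes, valid) per seed])`` tuples; the seed
    patterns live in the header and are not re-parsed here.
    """
    with open(path, "rb") as fh:
        magic = fh.read(len(_BINARY_MAGIC))
        if magic != _BINARY_MAGIC:
            raise ValueError(f"{path}: not a fishash binary container")
        (hlen,) = struct.unpack("<I", fh.read(4))
        header = json.loads(fh.read(hlen))
        if header.get("version") != _BINARY_VERSION:
            raise ValueError(f"{path}: unsupported container version")
        out = []
        for rec in header["records"]:
            streams = []
            for length in rec["lengths"]:
                hashes = np.frombuffer(fh.read(8 * length), dtype="<u8").astype(
                    np.uint64
                )
                nbytes = (length + 7) // 8
                valid = np.unpackbits(
                    np.frombuffer(fh.read(nbytes), dtype=np.uint8)
                )[:length].astype(bool)
                streams.append((hashes, valid))
            out.append((rec["id"], streams))
    return out
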