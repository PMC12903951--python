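"""Streaming FASTQ I/O and basic sequence utilities.

All coordinates in this package are 0-based, half-open. Quality scores are
Phred+33 only — the encoding emitted by every modern ONT basecaller; Phred+64
input is rejected rather than guessed. Reading and writing are streaming
(constant memory in the number of reads).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

_ALLOWED_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_GZIP_MAGIC = b"\x1f\x8b"


class FastqParseError(ValueError):
    """Raised when a FASTQ record cannot be decoded."""


@dataclass
class SequenceRecord:
    """One sequencing read: identifier, bases and per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: list[int]
    comment: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"record {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement(record: SequenceRecord) -> SequenceRecord:
    """Reverse-complement a record; qualities are reversed in lockstep."""
    return SequenceRecord(
        read_id=record.read_id,
        sequence=revcomp(record.sequence),
        qualities=record.qualities[::-1],
        comment=record.comment,
    )


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    handle = open(path, "rb")
    magic = handle.read(2)
    handle.seek(0)
    if magic == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=handle, mode="rb"))
    return io.TextIOWrapper(handle)


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a FASTQ file, plain or gzip (detected by magic bytes).

    Yields records in file order without loading the file into memory.
    Lowercase bases are uppercased; sequences are restricted to {A,C,G,T,N}.
    Raises :class:`FastqParseError` naming the failing record index.
    """
    index = 0
    with _open_maybe_gzip(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:  # malformed 4-line block
                raise FastqParseError(f"record {index} in {path}: {exc}") from exc
            parts = title.split(None, 1)
            read_id = parts[0]
            comment = parts[1] if len(parts) > 1 else None
            seq = seq.upper()
            if not set(seq) <= _ALLOWED_BASES:
                bad = sorted(set(seq) - _ALLOWED_BASES)
                raise FastqParseError(
                    f"record {index} ({read_id}) in {path}: "
                    f"invalid bases {''.join(bad)}"
                )
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"record {index} ({read_id}) in {path}: sequence/quality "
                    f"length mismatch ({len(seq)} vs {len(qual)})"
                )
            qualities = [ord(c) - 33 for c in qual]
            if any(q < 0 for q in qualities):
                raise FastqParseError(
                    f"record {index} ({read_id}) in {path}: quality character "
                    "below '!' — not Phred+33"
                )
            yield SequenceRecord(read_id, seq, qualities, comment)
            index += 1


def format_fastq(record: SequenceRecord) -> str:
    header = record.read_id
    if record.comment:
        header = f"{header} {record.comment}"
    qual = "".join(chr(q + 33) for q in record.qualities)
    return f"@{header}\n{record.sequence}\n+\n{qual}\n"


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> int:
    """Write records as Phred+33 FASTQ; gzip when the path ends in ``.gz``.

    Returns the number of records written. Gzip output is written with a
    zeroed mtime so identical inputs give byte-identical files.
    """
    path = Path(path)
    count = 0
    if path.suffix == ".gz":
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
                with io.TextIOWrapper(gz) as handle:
                    for record in records:
                        handle.write(format_fastq(record))
                        count += 1
    else:
        with open(path, "w") as handle:
            for record in records:
                handle.write(format_fastq(record))
                count += 1
    return count
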