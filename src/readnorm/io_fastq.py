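"""FASTQ/FASTA input and output.

Reads and writes 4-line FASTQ and FASTA records, plain or gzip-compressed
(gzip is detected by magic bytes on input and by a ``.gz`` suffix on
output), decodes phred quality strings, and keeps paired files
synchronized.  Parsing is delegated to Biopython's low-level iterators,
which are the fastest pure-Python FASTQ readers available; this module
wraps them with the package's error types and record bookkeeping.

The record id line is preserved verbatim (including any description after
the first whitespace) so that normalized output can be traced back to the
original file.  Sequences are uppercased on input; characters outside
``{A,C,G,T}`` are kept in the stored sequence and handled downstream
(k-mer extraction skips windows containing them).
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqParseError, ModeError, PairingError, PhredEncodingError

__all__ = [
    "Read",
    "ReadPair",
    "read_records",
    "read_pairs",
    "phred_values",
    "write_records",
    "write_pairs",
    "DEFAULT_PHRED_OFFSET",
]

DEFAULT_PHRED_OFFSET = 33  # Sanger / Illumina 1.8+

#: highest phred value representable in printable ASCII at offset 33
MAX_PHRED = 93


@dataclass(slots=True)
class Read:
    """One sequencing read: identifier, bases and (optional) phred string.

    ``qual`` is ``None`` for FASTA input.  When present it has exactly the
    same length as ``seq``.
    """

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FastqParseError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class ReadPair:
    """A mate pair; ``index`` is the ordinal of the pair in its input files."""

    left: Read
    right: Read
    index: int


def _is_gzip(path: str | os.PathLike) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def _open_text(path: str | os.PathLike):
    if _is_gzip(path):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: str | os.PathLike) -> str:
    """Return 'fastq' or 'fasta' from the first non-blank character."""
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                c = line[0]
                if c == "@":
                    return "fastq"
                if c == ">":
                    return "fasta"
                raise FastqParseError(
                    f"{path}: first record starts with {c!r}; "
                    "expected '@' (FASTQ) or '>' (FASTA)"
                )
    return "fastq"  # empty file: format irrelevant


def read_records(
    path: str | os.PathLike, format_hint: Optional[str] = None
) -> Iterator[Read]:
    """Yield :class:`Read` records from a FASTQ or FASTA file in file order.

    Parameters
    ----------
    path
        FASTQ or FASTA file, optionally gzip-compressed.
    format_hint
        ``"fastq"`` or ``"fasta"`` to skip auto-detection.

    Raises
    ------
    FastqParseError
        On truncated records or sequence/quality length mismatch; the
        message names the ordinal of the offending record.
    """
    fmt = format_hint or _sniff_format(path)
    if fmt not in ("fastq", "fasta"):
        raise FastqParseError(f"unknown format hint {fmt!r}")
    ordinal = 0
    with _open_text(path) as fh:
        try:
            if fmt == "fastq":
                for title, seq, qual in FastqGeneralIterator(fh):
                    ordinal += 1
                    if len(qual) != len(seq):
                        raise FastqParseError(
                            f"{path}: record {ordinal} ({title.split()[0]!r}): "
                            f"quality length {len(qual)} != sequence length {len(seq)}"
                        )
                    yield Read(id=title, seq=seq.upper(), qual=qual)
            else:
                for title, seq in SimpleFastaParser(fh):
                    ordinal += 1
                    yield Read(id=title, seq=seq.upper(), qual=None)
        except ValueError as exc:  # Biopython signals malformed records this way
            raise FastqParseError(
                f"{path}: malformed record after record {ordinal}: {exc}"
            ) from exc


def read_pairs(
    path1: str | os.PathLike, path2: str | os.PathLike
) -> Iterator[ReadPair]:
    """Yield synchronized :class:`ReadPair` objects from two mate files.

    Raises
    ------
    PairingError
        If the files hold different numbers of records; the message states
        both counts.
    """
    it1 = read_records(path1)
    it2 = read_records(path2)
    index = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            n1 = index + (r1 is not None) + sum(1 for _ in it1)
            n2 = index + (r2 is not None) + sum(1 for _ in it2)
            raise PairingError(
                f"paired files out of sync: {path1} has {n1} records, "
                f"{path2} has {n2}"
            )
        yield ReadPair(left=r1, right=r2, index=index)
        index += 1


def phred_values(qual: str, offset: int = DEFAULT_PHRED_OFFSET) -> list[int]:
    """Decode a phred string to per-base integer scores ``ord(c) - offset``.

    Raises
    ------
    PhredEncodingError
        If any character decodes below zero, which almost always means the
        offset is wrong for this file.
    """
    values = [ord(c) - offset for c in qual]
    if values and min(values) < 0:
        bad = min(qual)
        raise PhredEncodingError(
            f"quality character {bad!r} (ASCII {ord(bad)}) is below "
            f"offset {offset}; is the phred offset correct?"
        )
    return values


def write_records(reads: Iterable[Read], path: str | os.PathLike) -> None:
    """Write records to ``path``: FASTQ when qualities are present, FASTA
    otherwise.  A ``.gz`` suffix produces gzip output.  Round-tripping
    through :func:`read_records` reproduces ids, sequences and qualities
    exactly.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        as_fastq: Optional[bool] = None
        for read in reads:
            if as_fastq is None:
                as_fastq = read.qual is not None
            if (read.qual is not None) != as_fastq:
                raise ModeError(
                    "cannot mix quality-bearing and quality-less reads "
                    "in one output file"
                )
            if as_fastq:
                fh.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")
            else:
                fh.write(f">{read.id}\n{read.seq}\n")


def write_pairs(
    pairs: Iterable[ReadPair],
    path1: str | os.PathLike,
    path2: str | os.PathLike,
) -> None:
    """Write mate pairs to two files in lockstep."""
    pairs = list(pairs)
    write_records((p.left for p in pairs), path1)
    write_records((p.right for p in pairs), path2)


def reads_have_qualities(reads: Sequence[Read]) -> bool:
    """True when every read carries a quality string."""
    return all(r.qual is not None for r in reads)
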