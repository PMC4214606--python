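"""FASTA/FASTQ records and I/O.

Sequences live in memory as plain upper-case strings (``ACGTN`` for DNA,
one-letter amino-acid codes for proteins).  Internal coordinates are
everywhere 0-based half-open; 1-based inclusive coordinates exist only
inside the external-format readers and writers.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio.Seq import reverse_complement as _bio_revcomp

from .errors import ParseError

_DNA_ALPHABET = frozenset("ACGTN")


@dataclass
class SeqRecord:
    """A named sequence (scaffold, exon, protein, read...).

    ``id`` is a whitespace-free token unique within a file; ``description``
    is the free text after the first whitespace of the header.
    """

    id: str
    sequence: str
    description: str = ""
    quality: str | None = None  # FASTQ only, same length as sequence

    def __len__(self) -> int:
        return len(self.sequence)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return _bio_revcomp(seq)


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    """Open a text file, transparently handling ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def is_dna(seq: str) -> bool:
    return set(seq) <= _DNA_ALPHABET


def read_fasta(path: str | Path, *, dna: bool = True) -> Iterator[SeqRecord]:
    """Stream records from a FASTA file.

    Sequences are upper-cased on read.  With ``dna=True`` any symbol outside
    ``ACGTN`` is rejected.  Malformed headers, empty sequences and duplicate
    ids raise :class:`ParseError` naming the line.
    """
    spath = str(path)
    seen: set[str] = set()
    with _open_text(path) as fh:
        header_line = 0
        rec_id = None
        desc = ""
        chunks: list[str] = []

        def _emit() -> SeqRecord:
            seq = "".join(chunks).upper()
            if not seq:
                raise ParseError(f"empty sequence for record '{rec_id}'", spath, header_line)
            if dna and not is_dna(seq):
                bad = sorted(set(seq) - _DNA_ALPHABET)
                raise ParseError(
                    f"record '{rec_id}' contains non-ACGTN symbols {bad}", spath, header_line
                )
            return SeqRecord(rec_id, seq, desc)

        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if rec_id is not None:
                    yield _emit()
                head = line[1:].strip()
                if not head:
                    raise ParseError("empty FASTA header", spath, lineno)
                parts = head.split(None, 1)
                rec_id, desc = parts[0], (parts[1] if len(parts) > 1 else "")
                if rec_id in seen:
                    raise ParseError(f"duplicate record id '{rec_id}'", spath, lineno)
                seen.add(rec_id)
                header_line = lineno
                chunks = []
            else:
                if rec_id is None:
                    raise ParseError("sequence data before first FASTA header", spath, lineno)
                chunks.append(line.strip())
        if rec_id is not None:
            yield _emit()


def write_fasta(records: Iterable[SeqRecord], path: str | Path, line_width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream reads from a (possibly gzipped) FASTQ file."""
    spath = str(path)
    with _open_text(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            lineno = None  # line bookkeeping is cheap to skip in the hot loop
            head = head.rstrip("\n")
            if not head.startswith("@"):
                raise ParseError(f"expected '@' FASTQ header, got '{head[:30]}'", spath, lineno)
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+") or len(qual) != len(seq):
                raise ParseError(f"truncated FASTQ record '{head[1:]}'", spath, lineno)
            parts = head[1:].split(None, 1)
            yield SeqRecord(parts[0], seq.upper(), parts[1] if len(parts) > 1 else "", qual)


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            fh.write(f"@{head}\n{rec.sequence}\n+\n{qual}\n")
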