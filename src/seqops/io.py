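"""FASTA/FASTQ streaming readers and writers, and seeded read generators.

FASTA parsing delegates to Biopython's lazy ``SimpleFastaParser``; the
wrapper adds validation (the DNA alphabet), normalization (uppercasing
soft-masked bases, trimming headers at whitespace) and precise format
errors.  FASTQ records are strictly 4-line, read by a small dedicated loop
so that any text after the ``+`` separator is ignored and errors carry
exact line numbers.  Reading is gzip-transparent: the gzip magic bytes are
detected and decompressed on the fly.

The generators stand in for real sequencing data at whatever scale a test
or benchmark needs: i.i.d. bases from a weight vector, optional per-base N
dropout, constant qualities.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import gzip
import io as _io
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .encoding import DnaSequence

__all__ = [
    "FastaFormatError",
    "FastqRecord",
    "GeneratorSpec",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "generate_reads",
    "generate_reference",
]


class FastaFormatError(ValueError):
    """Malformed FASTA/FASTQ input; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class FastqRecord:
    """One sequencing read: identifier, bases, Phred+33 qualities."""

    name: str
    seq: DnaSequence
    qual: str

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise FastaFormatError(
                f"read {self.name!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )
        if any(not 33 <= ord(c) <= 126 for c in self.qual):
            raise FastaFormatError(f"read {self.name!r}: quality character out of Phred+33 range")


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    raw = open(path, "rb")
    if raw.read(2) == b"\x1f\x8b":  # gzip magic
        raw.seek(0)
        return _io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    raw.seek(0)
    return _io.TextIOWrapper(raw)


def read_fasta(path: str | Path) -> Iterator[tuple[str, DnaSequence]]:
    """Lazily yield ``(name, sequence)`` records.

    Multi-line sequences are joined; the name is the header text up to the
    first whitespace; lowercase bases are uppercased.  Sequence data before
    any header, or a header with no sequence, is a :class:`FastaFormatError`
    with the offending line number.
    """
    with _open_text(path) as fh:
        # SimpleFastaParser silently skips leading junk; reject it explicitly.
        lineno = 0
        first = None
        for line in fh:
            lineno += 1
            if line.strip():
                first = line
                break
        if first is None:
            return
        if not first.startswith(">"):
            raise FastaFormatError("sequence data before any '>' header", line=lineno)
        rest = itertools.chain([first], fh)  # line iterable; keeps parsing lazy
        for title, seq in SimpleFastaParser(rest):
            name = title.split(None, 1)[0] if title.split() else ""
            if not seq:
                raise FastaFormatError(f"record {name!r} has an empty sequence")
            yield name, DnaSequence(seq)


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, wrap: int = 60
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` (0 = no wrap)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            seq = str(seq)
            if wrap <= 0:
                fh.write(seq + "\n")
            else:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Lazily yield :class:`FastqRecord` from 4-line FASTQ records.

    The third line must start with ``+``; any text after it is ignored.
    Truncated records and quality/sequence length mismatches raise
    :class:`FastaFormatError` with the offending line number.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.strip():
                continue  # tolerate blank lines between records
            if not header.startswith("@"):
                raise FastaFormatError("expected '@' record header", line=lineno)
            lines = [fh.readline() for _ in range(3)]
            if any(not l for l in lines):
                raise FastaFormatError(
                    f"truncated record {header[1:].split()[0] if header[1:].split() else ''!r}",
                    line=lineno,
                )
            seq, plus, qual = (l.rstrip("\n") for l in lines)
            lineno += 3
            if not plus.startswith("+"):
                raise FastaFormatError("expected '+' separator line", line=lineno - 1)
            title = header[1:]
            name = title.split(None, 1)[0] if title.split() else ""
            if len(qual) != len(seq):
                raise FastaFormatError(
                    f"read {name!r}: quality length {len(qual)} != sequence length {len(seq)}",
                    line=lineno,
                )
            yield FastqRecord(name=name, seq=DnaSequence(seq), qual=qual)


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.name}\n{rec.seq}\n+\n{rec.qual}\n")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic short-read generator.

    Defaults emulate the shape of the benchmark corpus — 75 bp reads with
    uniform base composition and no N dropout — at whatever ``n_reads``
    the caller can afford.
    """

    n_reads: int
    read_length: int = 75
    base_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_weights) - 1.0) > 1e-9:
            raise ValueError("base_weights must sum to 1")
        if not 0.0 <= self.n_rate <= 1.0:
            raise ValueError("n_rate must be a probability")


def generate_reads(spec: GeneratorSpec) -> Iterator[FastqRecord]:
    """Yield ``spec.n_reads`` i.i.d. random reads, deterministically per seed.

    Bases are drawn independently from ``base_weights`` over ACGT, then each
    is replaced by N with probability ``n_rate``.  Qualities are the
    constant 'I' (Phred 40) — the benchmarks never consume them.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    qual = "I" * spec.read_length
    for i in range(spec.n_reads):
        draw = rng.choice(bases, size=spec.read_length, p=spec.base_weights)
        if spec.n_rate > 0:
            n_mask = rng.random(spec.read_length) < spec.n_rate
            draw = np.where(n_mask, np.array(b"N", dtype="S1"), draw)
        seq = draw.tobytes().decode("ascii")
        yield FastqRecord(name=f"read{i}", seq=DnaSequence(seq), qual=qual)


def generate_reference(length: int, seed: int = 0) -> DnaSequence:
    """A deterministic uniform ACGT sequence of the given length."""
    rng = np.random.default_rng(seed)
    draw = rng.integers(0, 4, size=length)
    return DnaSequence(np.frombuffer(b"ACGT", dtype="S1")[draw].tobytes().decode("ascii"))
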