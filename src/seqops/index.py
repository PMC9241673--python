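"""A hash index from k-mer codes to reference positions, with read seeding.

The index maps every N-free k-long window of a reference (stride 1) to the
sorted list of 0-based positions where it occurs — the classic hash-table
seeding structure of short-read aligners, with k = 20 by default.  Lookups
go through a two-call protocol: ``prefetch(km)`` is an advisory, semantically
inert hint that the entry for ``km`` is about to be needed, and
``lookup(km)`` performs the actual access.  Instrumentation counters and an
optional event trace record the (prefetch, lookup) order so schedulers that
interleave many in-flight queries can be observed doing so.

``seed_reads`` runs the seeding computation per read: k-merize at a step
(default k, i.e. non-overlapping), sum candidate loci over the read's
k-mers in the forward orientation and over their reverse complements, and
emit a :class:`SeedReport`.  It is expressible as a prefetch stage, so the
M-slot scheduler applies unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Generator, Iterable, Iterator, TextIO

from .encoding import DnaSequence, KmerValue, revcomp_kmer
from .ops import kmers
from .pipeline import DEFAULT_M, PrefetchStage, run_prefetch

__all__ = ["DEFAULT_INDEX_K", "KmerIndex", "SeedReport", "build_index", "seed_reads"]

#: Default seed length: the hash-table width used by SNAP-style seeding.
DEFAULT_INDEX_K = 20

_FORMAT_HEADER = "#seqops-kmer-index\tv1"


@dataclass
class SeedReport:
    """Candidate-locus totals for one read, both orientations."""

    name: str
    hits_forward: int
    hits_reverse: int


@dataclass
class KmerIndex:
    k: int
    entries: dict[int, list[int]] = field(default_factory=dict)
    reference_length: int = 0
    #: contig name -> offset of its first base in the concatenated reference
    contig_offsets: dict[str, int] = field(default_factory=dict)
    access_counter: int = 0
    prefetch_counter: int = 0
    #: optional hook receiving ("prefetch"|"lookup", code) events
    trace_hook: Callable[[str, int], None] | None = None

    def _check_k(self, km: KmerValue) -> None:
        if km.k != self.k:
            raise ValueError(f"index holds {self.k}-mers, got a {km.k}-mer")

    def lookup(self, km: KmerValue) -> list[int]:
        """Sorted 0-based reference positions of the k-mer (empty if absent)."""
        self._check_k(km)
        self.access_counter += 1
        if self.trace_hook is not None:
            self.trace_hook("lookup", km.code)
        return self.entries.get(km.code, [])

    def prefetch(self, km: KmerValue) -> None:
        """Advisory hint: no semantic effect, recorded for instrumentation."""
        self._check_k(km)
        self.prefetch_counter += 1
        if self.trace_hook is not None:
            self.trace_hook("prefetch", km.code)

    # -- persistence: sorted text table, one k-mer per line -----------------

    def save(self, fh: TextIO) -> None:
        """Write the index as a versioned text table: code TAB positions."""
        fh.write(f"{_FORMAT_HEADER}\tk={self.k}\treference_length={self.reference_length}\n")
        for code in sorted(self.entries):
            positions = ",".join(map(str, self.entries[code]))
            fh.write(f"{code}\t{positions}\n")

    @classmethod
    def load(cls, fh: TextIO) -> "KmerIndex":
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 4 or header[0] != "#seqops-kmer-index" or header[1] != "v1":
            raise ValueError("not a seqops k-mer index table (bad header)")
        k = int(header[2].removeprefix("k="))
        reference_length = int(header[3].removeprefix("reference_length="))
        entries: dict[int, list[int]] = {}
        for line in fh:
            code_s, _, pos_s = line.rstrip("\n").partition("\t")
            entries[int(code_s)] = [int(p) for p in pos_s.split(",")] if pos_s else []
        return cls(k=k, entries=entries, reference_length=reference_length)


def build_index(
    reference: str | Iterable[tuple[str, str]], k: int = DEFAULT_INDEX_K
) -> KmerIndex:
    """Index every N-free k-long window of the reference at stride 1.

    ``reference`` is a single sequence or an iterable of ``(name, seq)``
    contigs; contigs are concatenated and per-contig offsets recorded so
    positions can be mapped back.  Raises ``ValueError`` when the (total)
    reference is shorter than ``k``.
    """
    if isinstance(reference, (str, DnaSequence)):
        contigs: list[tuple[str, DnaSequence]] = [("ref", DnaSequence(reference))]
    else:
        contigs = [(name, DnaSequence(seq)) for name, seq in reference]
    offsets: dict[str, int] = {}
    pos = 0
    parts = []
    for name, seq in contigs:
        offsets[name] = pos
        pos += len(seq)
        parts.append(seq)
    concatenated = DnaSequence("".join(parts))
    if len(concatenated) < k:
        raise ValueError(f"reference length {len(concatenated)} is shorter than k={k}")
    entries: dict[int, list[int]] = {}
    for position, km in kmers(concatenated, k, stride=1):
        entries.setdefault(km.code, []).append(position)
    return KmerIndex(
        k=k,
        entries=entries,
        reference_length=len(concatenated),
        contig_offsets=offsets,
    )


def _read_kmers(ix: KmerIndex, seq: str, step: int) -> list[KmerValue]:
    return [km for _, km in kmers(seq, ix.k, stride=step)]


def seed_stage(ix: KmerIndex, step: int | None = None) -> PrefetchStage:
    """The per-read seeding task as a suspendable prefetch stage.

    Each task k-merizes its read, issues one prefetch hint (for the read's
    first k-mer), suspends, and on resumption sums candidate loci for the
    forward k-mers and their reverse complements.  Accepts ``(name, seq)``
    pairs or any object with ``name``/``seq`` attributes.
    """
    if step is None:
        step = ix.k

    def seed_one(read) -> Generator[None, None, SeedReport]:
        name, seq = read if isinstance(read, tuple) else (read.name, read.seq)
        kms = _read_kmers(ix, seq, step)
        if kms:
            ix.prefetch(kms[0])
        yield
        forward = sum(len(ix.lookup(km)) for km in kms)
        reverse = sum(len(ix.lookup(revcomp_kmer(km))) for km in kms)
        return SeedReport(name=name, hits_forward=forward, hits_reverse=reverse)

    return PrefetchStage(seed_one)


def seed_reads(
    ix: KmerIndex,
    reads: Iterable,
    step: int | None = None,
    prefetch: bool = False,
    M: int = DEFAULT_M,
) -> Iterator[SeedReport]:
    """Seed a stream of reads against the index, lazily.

    With ``prefetch=True`` the per-read tasks are interleaved by the M-slot
    scheduler; the reports' multiset is identical either way.
    """
    if step is not None and step < 1:
        raise ValueError("step must be >= 1")
    stage = seed_stage(ix, step)
    if prefetch:
        return run_prefetch(stage, reads, M=M)

    def serial() -> Iterator[SeedReport]:
        for read in reads:
            task = stage.fn(read)
            next(task)
            try:
                next(task)
            except StopIteration as stop:
                yield stop.value

    return serial()
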