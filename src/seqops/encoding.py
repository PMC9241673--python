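"""2-bit k-mer encoding, lookup tables, and complement/reverse operations.

A k-mer over {A, C, G, T} is packed into a ``2k``-bit unsigned integer, two
bits per base, first base in the most significant bit pair.  The base map is

    A = 00,  C = 01,  G = 10,  T = 11

which has two useful consequences:

* integer order on codes equals lexicographic order on k-mer strings, and
* complementation is bitwise NOT (``f(A) = ~f(T)`` and ``f(C) = ~f(G)``
  over two bits), so reversing a k-mer is just its reverse complement with
  every bit flipped.

Reverse complementation itself is table driven: a 256-entry table ``rc4``
holds the encoded reverse complement of every 4-mer, and an arbitrary k-mer
is reverse complemented by slicing it into 4-mer chunks, looking each chunk
up, and concatenating the results in reverse chunk order (because
``revcomp(s1 + s2) == revcomp(s2) + revcomp(s1)``).  When ``k`` is not a
multiple of 4 the k-mer is padded at its 3' end with A bases to the next
multiple of 4; the pad turns into leading T bases in the reverse complement,
which a final mask to the low ``2k`` bits removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MAX_K",
    "AmbiguousBaseError",
    "DnaSequence",
    "EncodingTables",
    "KmerValue",
    "TABLES",
    "build_tables",
    "decode_kmer",
    "encode_kmer",
    "revcomp_kmer",
    "reverse_kmer",
    "revcomp_seq",
]

#: Largest supported k-mer length.  Codes for k beyond a machine word rely on
#: Python's arbitrary-precision integers.
MAX_K = 1024

#: Sentinel stored in ``base2bit`` for bytes that are not a nucleotide.
INVALID_BASE = 0xFF

_ALPHABET = "ACGT"
_SEQ_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AmbiguousBaseError(ValueError):
    """A base outside {A, C, G, T} was found where a 2-bit code is required."""


class DnaSequence(str):
    """A validated DNA string over {A, C, G, T, N}.

    Lowercase (soft-masked) input is normalized to uppercase on
    construction; any other character raises ``ValueError``.  Instances are
    plain strings otherwise, so slicing and the usual string API apply.
    """

    __slots__ = ()

    def __new__(cls, bases: str = "") -> "DnaSequence":
        s = str(bases).upper()
        if not _SEQ_ALPHABET.issuperset(s):
            bad = next(c for c in s if c not in _SEQ_ALPHABET)
            raise ValueError(f"invalid nucleotide {bad!r} in sequence")
        return str.__new__(cls, s)

    def revcomp(self) -> "DnaSequence":
        return revcomp_seq(self)


@dataclass(frozen=True)
class KmerValue:
    """A k-mer stored as its length ``k`` and 2k-bit integer ``code``."""

    k: int
    code: int

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in 1..{MAX_K}, got {self.k}")
        if not 0 <= self.code < (1 << (2 * self.k)):
            raise ValueError(f"code {self.code} out of range for k={self.k}")

    def __str__(self) -> str:
        return str(decode_kmer(self))


@dataclass(frozen=True)
class EncodingTables:
    """The three lookup tables backing all k-mer conversions.

    rc4
        256 one-byte entries; entry ``i`` is the encoded reverse complement
        of the 4-mer whose code is ``i``.
    base2bit
        256 entries mapping an ASCII byte to its 2-bit base code, or the
        ``INVALID_BASE`` sentinel for non-nucleotide bytes.
    bit2base
        The 4 ASCII bases indexed by 2-bit code.
    """

    rc4: np.ndarray
    base2bit: np.ndarray
    bit2base: str


def _rc4_entry(code: int) -> int:
    # Complement = bitwise NOT; reverse = swap the four 2-bit fields.
    c = ~code & 0xFF
    return ((c & 0x03) << 6) | ((c & 0x0C) << 2) | ((c & 0x30) >> 2) | ((c & 0xC0) >> 6)


def build_tables() -> EncodingTables:
    """Build the rc4 / base2bit / bit2base lookup tables."""
    rc4 = np.array([_rc4_entry(i) for i in range(256)], dtype=np.uint8)
    base2bit = np.full(256, INVALID_BASE, dtype=np.uint8)
    for bits, base in enumerate(_ALPHABET):
        base2bit[ord(base)] = bits
        base2bit[ord(base.lower())] = bits
    return EncodingTables(rc4=rc4, base2bit=base2bit, bit2base=_ALPHABET)


#: Module-level tables, built once at import ("compile") time.
TABLES = build_tables()

# plain-list views of the tables for the per-base hot loops (scalar indexing
# into numpy arrays is an order of magnitude slower than list indexing)
_BASE2BIT: list[int] = TABLES.base2bit.tolist()
_RC4: list[int] = TABLES.rc4.tolist()


def encode_kmer(window: str, k: int | None = None) -> KmerValue:
    """Pack a k-long ACGT window into a :class:`KmerValue`.

    Raises :class:`AmbiguousBaseError` on any base outside {A, C, G, T}
    (N included) and ``ValueError`` if the window length differs from ``k``.
    """
    if k is None:
        k = len(window)
    if len(window) != k:
        raise ValueError(f"window length {len(window)} != k={k}")
    base2bit = _BASE2BIT
    code = 0
    for ch in window:
        o = ord(ch)
        bits = base2bit[o] if o < 256 else INVALID_BASE
        if bits == INVALID_BASE:
            raise AmbiguousBaseError(f"cannot 2-bit encode base {ch!r}")
        code = (code << 2) | bits
    return KmerValue(k=k, code=code)


def decode_kmer(km: KmerValue) -> DnaSequence:
    """Unpack a :class:`KmerValue` back into its ACGT string."""
    bit2base = TABLES.bit2base
    chars = []
    code = km.code
    for _ in range(km.k):
        chars.append(bit2base[code & 0x03])
        code >>= 2
    return DnaSequence("".join(reversed(chars)))


def revcomp_kmer(km: KmerValue) -> KmerValue:
    """Reverse complement a packed k-mer via the rc4 table.

    The code is padded with A bases (zero bits) at the 3' end up to a
    multiple of four bases, processed in 4-mer chunks through ``rc4`` in
    reverse chunk order, and finally masked to ``2k`` bits to drop the
    T bases the pad turned into.
    """
    rc4 = _RC4
    pad = (-km.k) % 4
    code = km.code << (2 * pad)
    out = 0
    for _ in range((km.k + pad) // 4):
        out = (out << 8) | rc4[code & 0xFF]
        code >>= 8
    return KmerValue(k=km.k, code=out & ((1 << (2 * km.k)) - 1))


def reverse_kmer(km: KmerValue) -> KmerValue:
    """Reverse a packed k-mer: bit-inverted reverse complement."""
    mask = (1 << (2 * km.k)) - 1
    return KmerValue(k=km.k, code=~revcomp_kmer(km).code & mask)


def revcomp_seq(s: str) -> DnaSequence:
    """Character-level reverse complement; N maps to N."""
    s = s if isinstance(s, DnaSequence) else DnaSequence(s)
    return DnaSequence(s.translate(_COMPLEMENT)[::-1])
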