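"""Sequence-level operators: k-merization, splitting, base counting,
palindrome tests and CpG-run extraction.

All coordinates are 0-based; intervals are half-open.  ``kmers`` feeds the
2-bit representation and therefore skips windows containing N (the code has
no room for ambiguity); ``split`` returns raw subsequences and keeps N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .encoding import DnaSequence, KmerValue, encode_kmer, revcomp_kmer, revcomp_seq

__all__ = [
    "CpGRegionSet",
    "kmers",
    "split",
    "base_counts",
    "gc_fraction",
    "is_self_revcomp",
    "is_symmetric_kmer",
    "cpg_regions",
]


def kmers(s: str, k: int, stride: int = 1) -> Iterator[tuple[int, KmerValue]]:
    """Lazily yield ``(position, KmerValue)`` for windows at 0, stride, 2*stride, ...

    Windows containing any non-ACGT base are skipped; the position grid
    still advances past them.  Empty if ``s`` is shorter than ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    for start in range(0, len(s) - k + 1, stride):
        window = s[start : start + k]
        try:
            yield start, encode_kmer(window, k)
        except ValueError:
            continue


def split(s: str, width: int, stride: int = 1) -> Iterator[DnaSequence]:
    """Lazily yield raw subsequences (N allowed) of ``width`` at the stride grid."""
    if width < 1:
        raise ValueError("width must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    s = s if isinstance(s, DnaSequence) else DnaSequence(s)
    for start in range(0, len(s) - width + 1, stride):
        yield DnaSequence(s[start : start + width])


def base_counts(s: str) -> dict[str, int]:
    """Counts of A, C, G, T and N; values sum to ``len(s)``."""
    s = s if isinstance(s, DnaSequence) else DnaSequence(s)
    counts = {b: 0 for b in "ACGTN"}
    for b in s:
        counts[b] += 1
    return counts


def gc_fraction(s: str) -> float:
    """Fraction of G+C among all bases; 0.0 for the empty sequence."""
    if len(s) == 0:
        return 0.0
    c = base_counts(s)
    return (c["G"] + c["C"]) / len(s)


def is_self_revcomp(s: str) -> bool:
    """True iff the sequence equals its own reverse complement.

    Always false for odd lengths (the middle base would have to be its own
    complement) and for sequences containing N (N complements to N but a
    specific base call cannot certify identity of opposite strands);
    both fall out of the direct string comparison.
    """
    s = s if isinstance(s, DnaSequence) else DnaSequence(s)
    return "N" not in s and s == revcomp_seq(s)


def is_symmetric_kmer(km: KmerValue) -> bool:
    """True iff the first k/2 bases equal the reverse complement of the last k/2.

    Equivalent to the decoded string being its own reverse complement.
    Raises ``ValueError`` for odd k.
    """
    if km.k % 2 != 0:
        raise ValueError(f"symmetry is defined for even k only, got k={km.k}")
    half_bits = km.k  # 2 * (k // 2)
    first = KmerValue(k=km.k // 2, code=km.code >> half_bits)
    second = KmerValue(k=km.k // 2, code=km.code & ((1 << half_bits) - 1))
    return first == revcomp_kmer(second)


@dataclass
class CpGRegionSet:
    """Maximal C/G runs containing at least one C and one G.

    ``regions`` are disjoint, sorted, half-open 0-based intervals, each of
    length >= 2 (a singleton run cannot contain both a C and a G).
    """

    regions: list[tuple[int, int]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.regions)

    @property
    def min_len(self) -> int:
        return min((e - s for s, e in self.regions), default=0)

    @property
    def max_len(self) -> int:
        return max((e - s for s, e in self.regions), default=0)


def cpg_regions(s: str) -> CpGRegionSet:
    """Extract maximal runs over {C, G} that contain both a C and a G.

    A run of only C (e.g. ``CCC``) or only G counts as no region at all.
    """
    s = s if isinstance(s, DnaSequence) else DnaSequence(s)
    regions: list[tuple[int, int]] = []
    start = None
    has_c = has_g = False
    for i, ch in enumerate(s):
        if ch == "C" or ch == "G":
            if start is None:
                start, has_c, has_g = i, False, False
            has_c |= ch == "C"
            has_g |= ch == "G"
        elif start is not None:
            if has_c and has_g:
                regions.append((start, i))
            start = None
    if start is not None and has_c and has_g:
        regions.append((start, len(s)))
    return CpGRegionSet(regions=regions)
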