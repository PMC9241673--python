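"""A wildcard pattern mini-language for DNA sequences.

Patterns are strings over ``A C G T _ .``: a nucleotide letter matches only
itself, ``_`` matches exactly one base of any kind (N included), and ``...``
(a run of dots whose length is a multiple of three) matches zero or more
bases of any kind.  Matching is anchored at both ends — a bare pattern must
account for the whole sequence; wrap it in ``...`` on either side to search
for a subsequence.

The matcher is an NFA simulation over token positions, O(len(s) * len(p))
time and O(len(p)) space, so adversarial gap-heavy patterns stay cheap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Hashable, Iterable, Optional

from .encoding import DnaSequence

__all__ = ["Token", "SeqPattern", "PatternSyntaxError", "parse_pattern", "matches", "match_dispatch"]


class PatternSyntaxError(ValueError):
    """Raised for characters outside the pattern alphabet or a ragged dot-run."""


class Token(enum.Enum):
    """Non-literal pattern tokens."""

    ANY_BASE = "_"  # exactly one base
    GAP = "..."  # zero or more bases


_LITERALS = frozenset("ACGT")


@dataclass(frozen=True)
class SeqPattern:
    """A parsed pattern: a tuple of literal bases and wildcard tokens."""

    tokens: tuple[object, ...]

    def __str__(self) -> str:
        return "".join(t if isinstance(t, str) else t.value for t in self.tokens)


def parse_pattern(text: str) -> SeqPattern:
    """Parse a pattern string; adjacent gaps collapse to one.

    Raises :class:`PatternSyntaxError` on any character outside
    ``{A, C, G, T, _, .}`` or a dot-run whose length is not a multiple of 3.
    """
    tokens: list[object] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in _LITERALS:
            tokens.append(ch)
            i += 1
        elif ch == "_":
            tokens.append(Token.ANY_BASE)
            i += 1
        elif ch == ".":
            j = i
            while j < len(text) and text[j] == ".":
                j += 1
            if (j - i) % 3 != 0:
                raise PatternSyntaxError(
                    f"dot-run of length {j - i} at position {i} is not a multiple of 3"
                )
            # any number of consecutive gaps is semantically one gap
            if not tokens or tokens[-1] is not Token.GAP:
                tokens.append(Token.GAP)
            i = j
        else:
            raise PatternSyntaxError(f"invalid pattern character {ch!r} at position {i}")
    return SeqPattern(tokens=tuple(tokens))


def _token_matches(tok: object, ch: str) -> bool:
    if tok is Token.ANY_BASE:
        return True  # any of A, C, G, T, N
    return tok == ch  # literal: its own (uppercase) base only


def matches(p: SeqPattern | str, s: str) -> bool:
    """Anchored match: does the pattern account for the entire sequence?"""
    if isinstance(p, str):
        p = parse_pattern(p)
    s = s if isinstance(s, DnaSequence) else DnaSequence(s)
    toks = p.tokens
    n = len(toks)

    # reachable[j]: tokens[:j] can match the prefix of s consumed so far
    reachable = [False] * (n + 1)
    reachable[0] = True
    for j in range(n):  # epsilon closure through gaps
        if reachable[j] and toks[j] is Token.GAP:
            reachable[j + 1] = True

    for ch in s:
        nxt = [False] * (n + 1)
        for j in range(n):
            if not reachable[j]:
                continue
            tok = toks[j]
            if tok is Token.GAP:
                nxt[j] = True  # gap absorbs the base
            elif _token_matches(tok, ch):
                nxt[j + 1] = True
        for j in range(n):
            if nxt[j] and toks[j] is Token.GAP:
                nxt[j + 1] = True
        reachable = nxt
        if not any(reachable):
            return False
    return reachable[n]


def match_dispatch(
    s: str, cases: Iterable[tuple[SeqPattern | str, Hashable]]
) -> Optional[Hashable]:
    """Return the tag of the first case whose pattern matches ``s``.

    Mirrors ordered ``match`` dispatch: cases are tried top to bottom and a
    trailing all-gap pattern acts as the default arm.  ``None`` if nothing
    matches.
    """
    for pattern, tag in cases:
        if matches(pattern, s):
            return tag
    return None
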