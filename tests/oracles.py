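"""Independent brute-force oracles: pure string/regex reimplementations that
share no code path with the bit-packed implementation under test."""

from __future__ import annotations

import re

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_VALUE = {"A": 0, "C": 1, "G": 2, "T": 3}


def string_revcomp(s: str) -> str:
    """Character-by-character reverse complement."""
    return "".join(_COMP[c] for c in reversed(s))


def arithmetic_encode(s: str) -> int:
    """Per-base positional arithmetic: code = sum f(b_i) * 4^(k-1-i)."""
    code = 0
    for i, ch in enumerate(s):
        code += _VALUE[ch] * 4 ** (len(s) - 1 - i)
    return code


def pattern_to_regex(text: str) -> re.Pattern:
    """Translate a pattern to an anchored regex over the ACGTN alphabet.

    Literal -> itself, '_' -> any single symbol, '...' -> any-symbol-star.
    A ragged dot-run raises ValueError just like the real parser.
    """
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in "ACGT":
            out.append(ch)
            i += 1
        elif ch == "_":
            out.append("[ACGTN]")
            i += 1
        elif ch == ".":
            j = i
            while j < len(text) and text[j] == ".":
                j += 1
            if (j - i) % 3 != 0:
                raise ValueError("ragged dot-run")
            out.append("[ACGTN]*")
            i = j
        else:
            raise ValueError(f"bad char {ch!r}")
    return re.compile("".join(out))


def regex_matches(pattern_text: str, s: str) -> bool:
    return pattern_to_regex(pattern_text).fullmatch(s) is not None


def brute_cpg_regions(s: str) -> list[tuple[int, int]]:
    """Regex segmentation: maximal [CG]+ runs containing both letters."""
    return [
        (m.start(), m.end())
        for m in re.finditer(r"[CG]+", s)
        if "C" in m.group() and "G" in m.group()
    ]


def brute_count_symmetric_16mers(seq: str, stride: int = 1) -> int:
    """String-level symmetric-16-mer count over one sequence."""
    n = 0
    for start in range(0, len(seq) - 16 + 1, stride):
        w = seq[start : start + 16]
        if "N" not in w and w == string_revcomp(w):
            n += 1
    return n


class BruteIndex:
    """String-keyed seeding index built by direct slicing, no bit packing."""

    def __init__(self, reference: str, k: int):
        self.k = k
        self.table: dict[str, list[int]] = {}
        for p in range(len(reference) - k + 1):
            w = reference[p : p + k]
            if "N" not in w:
                self.table.setdefault(w, []).append(p)

    def hits(self, read: str, step: int) -> tuple[int, int]:
        fwd = rev = 0
        for start in range(0, len(read) - self.k + 1, step):
            w = read[start : start + self.k]
            if "N" in w:
                continue
            fwd += len(self.table.get(w, ()))
            rev += len(self.table.get(string_revcomp(w), ()))
        return fwd, rev
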