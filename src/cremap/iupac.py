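"""Degenerate nucleotide patterns and dyads.

IUPAC one-letter codes describe sets of bases (``S`` = G/C, ``Y`` = C/T,
``R`` = A/G, ...).  A transcription-factor consensus such as the
CreA/CRE1 binding site ``SYGGRG`` is a string of such codes; a *dyad* is
an ordered pair of consensi separated by a bounded spacer, the classic
proxy for cooperative double binding sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


class InvalidPatternError(ValueError):
    """Raised when a pattern contains a non-IUPAC character."""


def validate_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    if not pattern:
        raise InvalidPatternError("empty pattern")
    bad = sorted(set(pattern) - set(IUPAC_CODES))
    if bad:
        raise InvalidPatternError(f"invalid IUPAC character(s) {bad!r} in {pattern!r}")
    return pattern


def pattern_to_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC consensus to a regex over A/C/G/T.

    Ambiguity codes become character classes listing concrete bases only,
    so an ``N`` *in the scanned sequence* never matches (unknown bases
    cannot be claimed as sites).
    """
    pattern = validate_pattern(pattern)
    parts = []
    for ch in pattern:
        bases = IUPAC_CODES[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence or IUPAC pattern."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:  # pragma: no cover - defensive
        raise InvalidPatternError(f"cannot complement character {exc}") from exc


def matches_base(code: str, base: str) -> bool:
    """Whether IUPAC ``code`` admits concrete ``base``."""
    return base in IUPAC_CODES[code]


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate motif, e.g. the CRE1 consensus ``SYGGRG``."""

    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", validate_pattern(self.pattern))

    def __len__(self) -> int:
        return len(self.pattern)

    def __str__(self) -> str:
        return self.pattern

    @property
    def regex(self) -> re.Pattern[str]:
        return pattern_to_regex(self.pattern)

    def reverse_complement(self) -> "IUPACPattern":
        return IUPACPattern(reverse_complement(self.pattern))


@dataclass(frozen=True)
class DyadSpec:
    """Ordered motif pair with a bounded spacer.

    ``max_gap`` bounds the number of bases between the end of the first
    match and the start of the second (gap anchor; a start-to-start
    anchor is selectable at scan time).
    """

    first: IUPACPattern
    second: IUPACPattern
    max_gap: int

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")

    def __str__(self) -> str:
        return f"{self.first}..{self.second}<={self.max_gap}"

    @property
    def span(self) -> int:
        """Maximal genomic footprint of one qualifying pair."""
        return len(self.first) + self.max_gap + len(self.second)
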