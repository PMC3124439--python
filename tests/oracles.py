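"""Independent brute-force oracles used to verify the implementation.

These deliberately share no code with the package's scanning,
enumeration, or adjustment routines.
"""

from fractions import Fraction
from math import comb

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def window_matches(pattern: str, window: str) -> bool:
    return len(window) == len(pattern) and all(
        b in IUPAC[c] for c, b in zip(pattern, window)
    )


def greedy_scan_oracle(pattern: str, seq: str) -> list[int]:
    """Left-to-right scan testing every window, consuming on a match."""
    positions = []
    i = 0
    L = len(pattern)
    while i + L <= len(seq):
        if window_matches(pattern, seq[i : i + L]):
            positions.append(i)
            i += L
        else:
            i += 1
    return positions


def all_matches_oracle(pattern: str, seq: str) -> list[int]:
    """Every matching window, overlaps included."""
    L = len(pattern)
    return [i for i in range(len(seq) - L + 1) if window_matches(pattern, seq[i : i + L])]


def dyad_count_oracle(first: str, second: str, max_gap: int, seq: str) -> int:
    """Exhaustive ordered-pair enumeration over the greedy match sets."""
    p1 = greedy_scan_oracle(first, seq)
    p2 = greedy_scan_oracle(second, seq)
    n = 0
    for i in p1:
        for j in p2:
            gap = j - (i + len(first))
            if 0 <= gap <= max_gap:
                n += 1
    return n


def hypergeom_upper_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact rational P(X >= k) for hypergeometric(N, K, n)."""
    total = comb(N, n)
    return Fraction(
        sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(n, K) + 1)), total
    )


def bh_stepup_oracle(pvalues):
    """Textbook step-up definition evaluated literally."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [None] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        value = min(prev, pvalues[i] * n / rank)
        adjusted[i] = value
        prev = value
    return adjusted


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"))[::-1]
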