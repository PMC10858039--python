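"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results by enumeration rather than
calling the implementation under test.
"""

from __future__ import annotations

import math


def _primitive(motif: str) -> bool:
    n = len(motif)
    return not any(n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n))


def brute_force_strs(seq: str, min_lengths=(9, 4, 4, 3, 3, 3)) -> set[tuple[int, int, int]]:
    """Every maximal perfect tandem run as (start, end, unit_size), found by
    testing every (start, unit size) pair."""
    seq = seq.upper()
    n = len(seq)
    found: set[tuple[int, int, int]] = set()
    for u in range(1, 7):
        for s in range(n - u + 1):
            motif = seq[s : s + u]
            if "N" in motif or not _primitive(motif):
                continue
            # left-maximality: the periodic region must not extend to s-1
            if s >= 1 and s - 1 + u < n and seq[s - 1] != "N" and seq[s - 1] == seq[s - 1 + u]:
                continue
            e = s + u
            while e < n and seq[e] != "N" and seq[e] == seq[e - u]:
                e += 1
            units = (e - s) // u
            if units >= min_lengths[u - 1]:
                found.add((s, s + u * units, u))
    return found


def hypergeometric_fisher_p(table) -> float:
    """Two-sided Fisher exact p by explicit hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def pmf(k: int) -> float:
        return (
            math.comb(row1, k)
            * math.comb(row2, col1 - k)
            / math.comb(n, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = pmf(a)
    total = 0.0
    for k in range(lo, hi + 1):
        p = pmf(k)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def binomial_tail_geq(k: int, n: int, p: float = 0.5) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))
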