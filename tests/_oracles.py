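"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exact integer arithmetic and
exhaustive enumeration — and shares no code with the implementation it
checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P by full enumeration of the
    hypergeometric support with exact integer probabilities (tables at
    most as probable as the observed one, exact ties included)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    num_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = comb(r1, k) * comb(r2, c1 - k)
        if num <= num_obs:
            total += num
    return float(Fraction(total, comb(n, c1)))


def longest_paths_oracle(
    parents: dict[str, set[str]]
) -> dict[str, tuple[int, int]]:
    """(depth, height) per term by exhaustive recursive path
    enumeration. Exponential; only for fixtures of <= ~50 terms."""
    children: dict[str, set[str]] = {t: set() for t in parents}
    for t, ps in parents.items():
        for p in ps:
            children[p].add(t)

    def depth(t: str) -> int:
        if not parents[t]:
            return 0
        return 1 + max(depth(p) for p in parents[t])

    def height(t: str) -> int:
        if not children[t]:
            return 0
        return 1 + max(height(k) for k in children[t])

    return {t: (depth(t), height(t)) for t in parents}


def ic_oracle(
    parents: dict[str, set[str]], corpus: list[set[str]]
) -> dict[str, float]:
    """IC by brute-force descendant-closure counting."""
    import math

    children: dict[str, set[str]] = {t: set() for t in parents}
    for t, ps in parents.items():
        for p in ps:
            children[p].add(t)

    def descendants_with_self(t: str) -> set[str]:
        out = {t}
        for k in children[t]:
            out |= descendants_with_self(k)
        return out

    n = len(corpus)
    counts = {
        t: sum(1 for s in corpus if s & descendants_with_self(t))
        for t in parents
    }
    observed = [c for c in counts.values() if c > 0]
    max_ic = max((-math.log(c / n) for c in observed), default=0.0)
    return {
        t: (-math.log(c / n) if c > 0 else max_ic)
        for t, c in counts.items()
    }


def lin_bma_oracle(
    parents: dict[str, set[str]],
    ic: dict[str, float],
    set_a: set[str],
    set_b: set[str],
) -> float:
    """Best-match-average Lin similarity by exhaustive pair evaluation."""

    def ancestors_with_self(t: str) -> set[str]:
        out = {t}
        for p in parents[t]:
            out |= ancestors_with_self(p)
        return out

    def lin(t1: str, t2: str) -> float:
        common = ancestors_with_self(t1) & ancestors_with_self(t2)
        best = max(ic[t] for t in common)
        denom = ic[t1] + ic[t2]
        return 0.0 if denom <= 0 else 2 * best / denom

    fwd = sum(max(lin(x, y) for y in set_b) for x in set_a) / len(set_a)
    rev = sum(max(lin(x, y) for x in set_a) for y in set_b) / len(set_b)
    return 0.5 * (fwd + rev)
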