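"""Independent oracles used to cross-check the implementations.

These deliberately share no code with the package: the Fisher p is an
explicit hypergeometric enumeration, theta-pi is a literal count of
pairwise allele differences, and the alignment score is a memoized
exhaustive recursion over edit operations.
"""

from functools import lru_cache
from itertools import combinations
from math import comb, inf


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(k: int) -> float:
        # P(first cell = k) under the hypergeometric null
        return comb(row1, k) * comb(row2, col1 - k) / comb(n, col1)

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


def pi_pairwise(genotypes) -> float:
    """Mean pairwise allele differences among the called diploid genotypes.

    ``genotypes`` uses the package codes 0/1/2 (= ALT dosage); missing
    calls (-1) are excluded.
    """
    alleles: list[int] = []
    for g in genotypes:
        if g == -1:
            continue
        alleles += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(g)]
    pairs = list(combinations(alleles, 2))
    if not pairs:
        return 0.0
    return sum(x != y for x, y in pairs) / len(pairs)


def align_score_bruteforce(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal global score; a length-L gap costs gap_open + L*gap_extend."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> float:
        # best score over alignments of a[:i], b[:j] whose final column is
        # ``last`` ('M' diagonal, 'A' gap in b, 'B' gap in a, 'S' start)
        if i == 0 and j == 0:
            return 0.0 if last == "S" else -inf
        if last == "S":
            return -inf
        if last == "M":
            if i == 0 or j == 0:
                return -inf
            sub = match if a[i - 1] == b[j - 1] else mismatch
            return max(best(i - 1, j - 1, p) for p in "MABS") + sub
        if last == "A":
            if i == 0:
                return -inf
            return max(
                best(i - 1, j, p)
                + gap_extend
                + (0.0 if p == "A" else gap_open)
                for p in "MABS"
            )
        if j == 0:
            return -inf
        return max(
            best(i, j - 1, p) + gap_extend + (0.0 if p == "B" else gap_open)
            for p in "MABS"
        )

    return max(best(len(a), len(b), p) for p in "MAB")
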