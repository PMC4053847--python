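"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations (quadratic DP, exhaustive
enumeration) kept separate from the package code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def naive_local_affine_score(a: str, b: str, gap_open: int = 11,
                             gap_extend: int = 1) -> int:
    """Smith-Waterman with affine gaps (Gotoh), plain O(nm) loops.

    A gap of length g costs gap_open + g * gap_extend, i.e. the first
    gap character costs gap_open + gap_extend.
    """
    n, m = len(a), len(b)
    first = gap_open + gap_extend
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def exact_hypergeom_upper(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws.

    The background is {0..N-1} with items 0..K-1 carrying the term.
    Feasible only for small N (<= 12 in the tests).
    """
    hits = 0
    total = 0
    carriers = set(range(K))
    for draw in combinations(range(N), n):
        total += 1
        if len(carriers.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def weighted_degree_representatives(species_of: dict[str, str],
                                    edges: list[tuple[str, str, float]],
                                    members: set[str]) -> dict[str, str]:
    """Per-species member with maximal summed incident edge weight,
    computed by direct accumulation; ties to the smallest gene id."""
    degree = {m: 0.0 for m in members}
    for a, b, w in edges:
        if a in members and b in members:
            degree[a] += w
            degree[b] += w
    out: dict[str, str] = {}
    for sp in sorted({species_of[m] for m in members}):
        candidates = [m for m in members if species_of[m] == sp]
        out[sp] = min(candidates, key=lambda g: (-degree[g], g))
    return out
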