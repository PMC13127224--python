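"""Independent brute-force oracles used to validate the fast paths.

These deliberately share no code with the package implementation:
plain-Python Gotoh dynamic programming for alignment scores, O(n^2)
transitive closure for interval chaining, and a regex for sequons.
"""

from __future__ import annotations

import re

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def sw_affine_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Exhaustive local affine-gap DP; gap of length g costs open+(g-1)*extend."""
    n, m = len(a), len(b)
    best = 0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            sub = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, sub + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            best = max(best, M[i][j])
    return int(best)


def nw_affine_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Exhaustive global affine-gap DP with penalized end gaps."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
            sub = _B62[a[i - 1], b[j - 1]]
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = sub + prev
    return int(max(M[n][m], X[n][m], Y[n][m]))


def interval_closure(intervals: list[tuple[int, int]], max_gap: int) -> list[set[int]]:
    """Transitive closure of the 'edge distance < max_gap' relation via
    union-find over all O(n^2) pairs; returns index partitions."""
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            gap = max(a[0], b[0]) - min(a[1], b[1])
            if gap < max_gap:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=min)


SEQUON_RE = re.compile(r"(?=(N[^P][ST]))")


def sequon_positions(peptide: str) -> list[int]:
    return [m.start() for m in SEQUON_RE.finditer(peptide)]
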