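"""Naive reference implementations used as independent validation oracles.

Each routine here is written in the most transparent way possible (explicit
dynamic programs, exhaustive scans) and deliberately shares no code with
the optimized paths it validates: `sw_score_bruteforce` against the local
aligner, `dbscan_bruteforce` against the density clustering, and
`optics_order_bruteforce` against the reachability ordering.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_MATRIX_CACHE: dict = {}


def _score(matrix_name: str, a: str, b: str) -> float:
    if matrix_name not in _MATRIX_CACHE:
        _MATRIX_CACHE[matrix_name] = substitution_matrices.load(matrix_name)
    if "X" in (a, b):
        return 0.0
    return float(_MATRIX_CACHE[matrix_name][a, b])


def sw_score_bruteforce(query: str, target: str, gap_open: float = 11.0,
                        gap_extend: float = 1.0,
                        matrix_name: str = "BLOSUM62") -> float:
    """Smith-Waterman best local score by the textbook three-state affine
    DP (a gap of length k costs open + (k-1) * extend)."""
    n, m = len(query), len(target)
    neg = -1e18
    # M: ends in a match/mismatch; X: gap in target (query consumed);
    # Y: gap in query (target consumed)
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[:, 0] = M[0, :] = 0.0
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _score(matrix_name, query[i - 1], target[j - 1])
            M[i, j] = max(0.0, M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


def nw_score_bruteforce(query: str, target: str, gap_open: float = 11.0,
                        gap_extend: float = 1.0,
                        matrix_name: str = "BLOSUM62") -> float:
    """Global affine alignment score (no free end gaps), same conventions."""
    n, m = len(query), len(target)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _score(matrix_name, query[i - 1], target[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


def dbscan_bruteforce(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Exhaustive DBSCAN: core test by pairwise scan, clusters by repeated
    closure over core points, border points to the lowest cluster index."""
    n = len(points)
    def dist(i, j):
        return float(np.linalg.norm(points[i] - points[j]))

    neighbors = [[j for j in range(n) if dist(i, j) <= eps] for i in range(n)]
    core = [len(neighbors[i]) >= min_pts for i in range(n)]
    labels = [-1] * n
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        members = {i}
        changed = True
        while changed:
            changed = False
            for p in list(members):
                for q in neighbors[p]:
                    if core[q] and q not in members:
                        members.add(q)
                        changed = True
        for p in members:
            labels[p] = cluster
        cluster += 1
    for i in range(n):
        if core[i] or labels[i] != -1:
            continue
        options = [labels[q] for q in neighbors[i] if core[q] and labels[q] >= 0]
        if options:
            labels[i] = min(options)
    return np.array(labels)


def optics_order_bruteforce(points: np.ndarray, min_pts: int
                            ) -> tuple[list, list, list]:
    """Exhaustive OPTICS sweep: (ordering, reachability, core distances).

    Start each sweep at the lowest-index unprocessed point; repeatedly emit
    the unprocessed point with minimal reachability (ties to lowest index)
    and relax reachabilities through it.
    """
    n = len(points)
    def dist(i, j):
        return float(np.linalg.norm(points[i] - points[j]))

    core = []
    for i in range(n):
        ds = sorted(dist(i, j) for j in range(n))
        core.append(ds[min_pts - 1])
    reach = [float("inf")] * n
    done = [False] * n
    ordering = []
    for _ in range(n):
        best, best_r = None, float("inf")
        for i in range(n):
            if done[i]:
                continue
            if best is None or reach[i] < best_r:
                best, best_r = i, reach[i]
        done[best] = True
        ordering.append(best)
        for j in range(n):
            if done[j]:
                continue
            r = max(core[best], dist(best, j))
            if r < reach[j]:
                reach[j] = r
    return ordering, reach, core
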