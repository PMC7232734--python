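"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (triple loops, exact rational
arithmetic, exhaustive enumeration) kept separate from the package code
they check.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np


def naive_tom(A: np.ndarray) -> np.ndarray:
    """Topological overlap by direct triple loop over shared neighbours."""
    n = A.shape[0]
    out = np.eye(n)
    for m in range(n):
        for q in range(n):
            if m == q:
                continue
            l = sum(A[m, u] * A[u, q] for u in range(n) if u != m and u != q)
            km = sum(A[m, u] for u in range(n) if u != m)
            kq = sum(A[q, u] for u in range(n) if u != q)
            denom = min(km, kq) + 1.0 - A[m, q]
            out[m, q] = (l + A[m, q]) / denom if denom != 0 else 0.0
    return out


def naive_upgma_heights(D: np.ndarray) -> list[float]:
    """Merge heights of quadratic-time textbook UPGMA, sorted ascending."""
    D = D.astype(float).copy()
    n = D.shape[0]
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    nxt = n
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        si, sj = sizes[i], sizes[j]
        sizes[nxt] = si + sj
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(k, nxt)] = (si * dik + sj * djk) / (si + sj)
        active = [k for k in active if k not in (i, j)] + [nxt]
        dist = {
            (a, b): v
            for (a, b), v in dist.items()
            if a in active and b in active
        }
        nxt += 1
    return sorted(heights)


@lru_cache(maxsize=None)
def _comb(n: int, k: int) -> int:
    return comb(n, k)


def exact_hypergeom_upper(n_universe: int, n_term: int, n_query: int, overlap: int) -> Fraction:
    """P(X >= overlap) for X ~ Hypergeometric(N, K, q), exact rational."""
    if overlap <= 0:
        return Fraction(1)
    hi = min(n_term, n_query)
    if overlap > hi:
        return Fraction(0)
    den = _comb(n_universe, n_query)
    num = sum(
        _comb(n_term, x) * _comb(n_universe - n_term, n_query - x)
        for x in range(overlap, hi + 1)
        if n_query - x <= n_universe - n_term
    )
    return Fraction(num, den)


def exact_fisher_upper(table: tuple[int, int, int, int]) -> Fraction:
    """One-sided (enrichment) Fisher exact p for a 2x2 table, exact rational."""
    both, a_only, b_only, neither = table
    n = both + a_only + b_only + neither
    return exact_hypergeom_upper(n, both + a_only, both + b_only, both)


def brute_force_max_clique_size(n: int, edges: set[tuple[int, int]]) -> int:
    """Maximum clique size by enumerating all 2^n vertex subsets."""
    adj = [0] * n
    for u, v in edges:
        adj[u] |= 1 << v
        adj[v] |= 1 << u
    best = 0
    for mask in range(1, 1 << n):
        size = mask.bit_count()
        if size <= best:
            continue
        ok = True
        rest = mask
        while rest:
            v = (rest & -rest).bit_length() - 1
            rest &= rest - 1
            if (mask & ~(1 << v)) & ~adj[v]:
                ok = False
                break
        if ok:
            best = size
    return best


def jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b) if (a or b) else 1.0
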