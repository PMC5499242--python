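"""Independent brute-force oracles for small graphs.

Everything here works directly from a weight matrix by exhaustive
enumeration (all simple paths, explicit loops over the defining
formulas) and deliberately shares no code with the package's
implementations.  Intended for n <= 8.
"""

from __future__ import annotations

import numpy as np


def enumerate_simple_paths(w: np.ndarray, src: int, dst: int):
    """Yield every simple path src -> dst as a list of nodes."""
    n = w.shape[0]
    stack = [(src, [src])]
    while stack:
        node, path = stack.pop()
        if node == dst:
            yield path
            continue
        for nxt in range(n):
            if w[node, nxt] > 0 and nxt not in path:
                stack.append((nxt, path + [nxt]))


def path_length(w: np.ndarray, path: list[int]) -> float:
    return sum(1.0 / w[a, b] for a, b in zip(path, path[1:]))


def oracle_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest weighted distance by exhaustive path enumeration."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            best = np.inf
            for path in enumerate_simple_paths(w, i, j):
                best = min(best, path_length(w, path))
            d[i, j] = d[j, i] = best
    return d


def oracle_betweenness(w: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Unnormalized betweenness by enumerating and counting shortest paths.

    Endpoints excluded; each unordered pair contributes once; with g
    shortest paths between a pair, a node interior to c of them gains
    c / g.
    """
    n = w.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            lengths_paths = [
                (path_length(w, p), p) for p in enumerate_simple_paths(w, s, t)
            ]
            if not lengths_paths:
                continue
            best = min(length for length, _ in lengths_paths)
            shortest = [p for length, p in lengths_paths if length <= best + tol]
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc


def oracle_efficiency(w: np.ndarray) -> np.ndarray:
    """Transfer efficiency by explicit loops over ordered neighbor pairs."""
    n = w.shape[0]
    d = oracle_distances(w)
    e = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0 and j != i]
        deg = len(nb)
        if deg < 2:
            continue
        total = 0.0
        for j in nb:
            for h in nb:
                if j != h and np.isfinite(d[j, h]) and d[j, h] > 0:
                    total += 1.0 / d[j, h]
        e[i] = total / (deg * (deg - 1)) / n
    return e


def oracle_rc(w: np.ndarray) -> np.ndarray:
    """RC index straight from its defining sum."""
    n = w.shape[0]
    deg = np.array([sum(1 for j in range(n) if w[i, j] > 0 and j != i) for i in range(n)])
    strength = w.sum(axis=1)
    k_bar = deg.mean()
    s_bar = strength.mean()
    e = oracle_efficiency(w)
    rc = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i:
                acc += deg[j] * w[j, i] * e[j]
        rc[i] = e[i] * acc / (s_bar * k_bar**2)
    return rc


def oracle_clustering(w: np.ndarray) -> np.ndarray:
    """Binary clustering coefficient by explicit neighbor-pair counting."""
    n = w.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0 and j != i]
        k = len(nb)
        if k < 2:
            continue
        links = sum(
            1 for a in range(k) for b in range(a + 1, k) if w[nb[a], nb[b]] > 0
        )
        c[i] = 2.0 * links / (k * (k - 1))
    return c


def oracle_global_efficiency(w: np.ndarray) -> float:
    """Mean inverse shortest distance by explicit double loop."""
    n = w.shape[0]
    d = oracle_distances(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))
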