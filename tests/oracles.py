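"""Independent brute-force oracles for graph metrics.

These deliberately avoid the package's algorithms (and networkx): shortest
paths are enumerated explicitly over all simple paths, and clustering is
counted triangle by triangle, so they are only usable on tiny graphs.
"""

from itertools import permutations

import numpy as np


def _all_simple_paths(adj: np.ndarray, src: int, dst: int):
    """Every simple path from src to dst by depth-first enumeration."""
    n = adj.shape[0]
    paths = []

    def extend(path):
        last = path[-1]
        if last == dst:
            paths.append(list(path))
            return
        for nxt in range(n):
            if adj[last, nxt] and nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([src])
    return paths


def brute_force_betweenness(adj: np.ndarray) -> np.ndarray:
    """Betweenness by explicit enumeration of all shortest paths.

    For each unordered pair, every simple path is enumerated, the shortest
    length found, and each interior node of each shortest path credited
    with 1/(number of shortest paths).
    """
    n = adj.shape[0]
    bc = np.zeros(n)
    for j in range(n):
        for k in range(j + 1, n):
            paths = _all_simple_paths(adj, j, k)
            if not paths:
                continue
            dmin = min(len(p) for p in paths)
            shortest = [p for p in paths if len(p) == dmin]
            for p in shortest:
                for interior in p[1:-1]:
                    bc[interior] += 1.0 / len(shortest)
    return bc


def brute_force_clustering(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering by exhaustive neighbor-pair triangle counting."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a in range(k) for b in range(a + 1, k)
                    if adj[nbrs[a], nbrs[b]])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def brute_force_path_length(adj: np.ndarray) -> float:
    """Mean pairwise distance via enumerated shortest simple paths."""
    n = adj.shape[0]
    total, pairs = 0.0, 0
    for j in range(n):
        for k in range(j + 1, n):
            paths = _all_simple_paths(adj, j, k)
            if not paths:
                raise ValueError("disconnected")
            total += min(len(p) for p in paths) - 1
            pairs += 1
    return total / pairs


def random_connected_graph(rng: np.random.Generator, n: int,
                           p: float = 0.5) -> np.ndarray:
    """Small random connected adjacency matrix (rejection sampling)."""
    while True:
        a = rng.random((n, n)) < p
        a = np.triu(a, 1)
        a = a | a.T
        # connectivity via repeated neighbor expansion
        seen = {0}
        frontier = [0]
        while frontier:
            nxt = [j for i in frontier for j in np.nonzero(a[i])[0]
                   if j not in seen]
            seen.update(nxt)
            frontier = nxt
        if len(seen) == n:
            return a
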