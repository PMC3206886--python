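"""Small-world metrics, betweenness centrality, and degree-preserving nulls.

All quantities are defined on undirected, unweighted graphs:

* clustering coefficient ``C_i = 2 E_i / (k_i (k_i - 1))`` — the fraction of
  a node's neighbor pairs that are themselves connected — averaged over
  nodes to give the network clustering ``C`` (nodes with degree < 2
  contribute ``C_i = 0``, a documented convention that keeps ``C`` defined
  at sparse densities);
* characteristic path length ``L`` — the mean shortest-path (edge count)
  distance over all unordered node pairs of a connected graph;
* betweenness centrality ``B_i`` — for each node, the sum over node pairs
  of the fraction of their shortest paths passing through it as an interior
  node, reported as raw (unnormalized) pair counts;
* small-worldness — ``gamma = C / C_rand`` and ``lambda = L / L_rand``
  against an ensemble of degree-preserving rewired null graphs, summarized
  by the scalar ``sigma = gamma / lambda`` (> 1 for small-world networks).

The null model randomizes by repeated double-edge swaps, which keep every
node's degree exactly while destroying the neighborhood structure; swaps
that would disconnect the graph are rolled back, so path length stays
defined on every realization.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .graph import BinaryGraph

__all__ = [
    "NodalMetrics",
    "GlobalMetrics",
    "NullEnsemble",
    "clustering_vector",
    "nodal_clustering",
    "network_clustering",
    "characteristic_path_length",
    "betweenness",
    "rewire_preserving_degree",
    "small_world_metrics",
    "nodal_metrics",
]


@dataclass
class NodalMetrics:
    """Per-node metric vectors in the graph's node order."""

    clustering: np.ndarray
    betweenness: np.ndarray
    degree: np.ndarray
    region_labels: tuple[str, ...]


@dataclass
class NullEnsemble:
    """Clustering and path length of each rewired null realization."""

    c_values: np.ndarray
    l_values: np.ndarray
    seed: int

    @property
    def n_random(self) -> int:
        return len(self.c_values)


@dataclass
class GlobalMetrics:
    """Whole-network small-world summary.

    ``gamma = C / C_rand``, ``lambda_ = L / L_rand``, ``sigma = gamma /
    lambda_``, with ``C_rand`` and ``L_rand`` the null-ensemble means.
    """

    C: float
    L: float
    C_rand: float
    L_rand: float
    gamma: float
    lambda_: float
    sigma: float


def clustering_vector(g: BinaryGraph) -> np.ndarray:
    """Per-node clustering coefficients (degree < 2 nodes get 0)."""
    a = g.adjacency.astype(np.float64)
    k = a.sum(axis=1)
    # closed triangles through each node = diag(A^3) / 2
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def nodal_clustering(g: BinaryGraph, node: int) -> float:
    """Clustering coefficient of one node."""
    if not 0 <= node < g.n_nodes:
        raise ValueError(f"node {node} not in graph of size {g.n_nodes}")
    return float(clustering_vector(g)[node])


def network_clustering(g: BinaryGraph) -> float:
    """Network clustering C: the arithmetic mean of the nodal coefficients."""
    if g.n_nodes < 1:
        raise ValueError("graph has no nodes")
    return float(clustering_vector(g).mean())


def _distance_matrix(g: BinaryGraph) -> np.ndarray:
    return shortest_path(csr_matrix(g.adjacency.astype(np.int8)),
                         method="D", unweighted=True, directed=False)


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean shortest-path distance over all unordered node pairs.

    Raises on a disconnected graph rather than substituting infinities or a
    harmonic mean — the pipeline guarantees connectedness upstream.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    d = _distance_matrix(g)
    iu = np.triu_indices(n, k=1)
    dists = d[iu]
    if np.isinf(dists).any():
        raise ValueError("graph is disconnected; path length undefined")
    return float(dists.mean())


def betweenness(g: BinaryGraph) -> np.ndarray:
    """Betweenness centrality of every node (Brandes accumulation).

    ``B_i = sum over unordered pairs {j, k} (j, k != i) of the fraction of
    shortest j-k paths with i interior``.  Values are raw pair counts, not
    normalized.  Requires a connected graph.
    """
    n = g.n_nodes
    adj = [np.nonzero(g.adjacency[i])[0].tolist() for i in range(n)]
    if n > 1 and not g.is_connected():
        raise ValueError("betweenness requires a connected graph")
    bc = np.zeros(n)
    for s in range(n):
        # single-source shortest-path counts by BFS
        stack: list[int] = []
        pred: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = [s]
        for v in queue:
            stack.append(v)
            dv = dist[v]
            sv = sigma[v]
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dv + 1
                    queue.append(w)
                if dist[w] == dv + 1:
                    sigma[w] += sv
                    pred[w].append(v)
        # dependency accumulation in reverse BFS order
        delta = np.zeros(n)
        for w in reversed(stack):
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in pred[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered pair was counted from both endpoints


def nodal_metrics(g: BinaryGraph) -> NodalMetrics:
    """Clustering, betweenness, and degree for every node."""
    return NodalMetrics(clustering_vector(g), betweenness(g), g.degrees(),
                        g.region_labels)


def rewire_preserving_degree(g: BinaryGraph, n_swaps_per_edge: int = 10,
                             seed: int | None = None) -> BinaryGraph:
    """Degree-preserving randomization by repeated double-edge swaps.

    Attempts ``n_swaps_per_edge * |E|`` swaps; each picks two edges
    (a, b), (c, d) and rewires to (a, d), (c, b) unless that would create a
    self-loop or duplicate edge.  Connectivity is audited in windows of
    swaps: if a window leaves the graph disconnected, its swaps are rolled
    back and retried one-by-one with an explicit connectivity check, so the
    result is always connected when the input is.
    """
    n = g.n_nodes
    edges = g.edge_list()
    m = len(edges)
    if m < 2:
        raise ValueError("graph too small to rewire (needs >= 2 edges)")
    degrees_in = np.sort(g.degrees())
    was_connected = g.is_connected()
    rng = random.Random(seed)
    adj = {i: set(np.nonzero(g.adjacency[i])[0].tolist()) for i in range(n)}

    def do_swap(e1: int, e2: int) -> tuple | None:
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, b), (c, d) -> (a, d), (c, b)
        if len({a, b, c, d}) < 4:
            return None
        if d in adj[a] or b in adj[c]:
            return None
        adj[a].discard(b); adj[b].discard(a)
        adj[c].discard(d); adj[d].discard(c)
        adj[a].add(d); adj[d].add(a)
        adj[c].add(b); adj[b].add(c)
        edges[e1] = (a, d)
        edges[e2] = (c, b)
        return (e1, e2, (a, b), (c, d))

    def undo(rec: tuple) -> None:
        e1, e2, (a, b), (c, d) = rec
        a2, d2 = edges[e1]
        c2, b2 = edges[e2]
        adj[a2].discard(d2); adj[d2].discard(a2)
        adj[c2].discard(b2); adj[b2].discard(c2)
        adj[a].add(b); adj[b].add(a)
        adj[c].add(d); adj[d].add(c)
        edges[e1] = (a, b)
        edges[e2] = (c, d)

    def connected() -> bool:
        seen = {0}
        frontier = [0]
        while frontier:
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if w not in seen:
                        seen.add(w)
                        nxt.append(w)
            frontier = nxt
        return len(seen) == n

    target = n_swaps_per_edge * m
    attempted = 0
    window: list[tuple] = []
    window_size = max(m // 2, 1)
    while attempted < target:
        budget = min(window_size, target - attempted)
        window.clear()
        for _ in range(budget):
            rec = do_swap(rng.randrange(m), rng.randrange(m))
            attempted += 1
            if rec is not None:
                window.append(rec)
        if was_connected and window and not connected():
            # a swap in this window broke connectivity: roll the whole
            # window back, refund its attempts, and retry swap-by-swap
            # with an audit after every single swap
            for rec in reversed(window):
                undo(rec)
            attempted -= budget
            retry = min(budget, target - attempted)
            for _ in range(retry):
                rec = do_swap(rng.randrange(m), rng.randrange(m))
                attempted += 1
                if rec is not None and not connected():
                    undo(rec)
            window_size = max(window_size // 2, 1)
        else:
            window_size = min(window_size * 2, m)

    out = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        out[a, b] = out[b, a] = True
    result = BinaryGraph(out, g.region_labels, g.sparsity)
    if not np.array_equal(np.sort(result.degrees()), degrees_in):
        raise AssertionError("degree sequence changed during rewiring")
    if result.n_edges != m:
        raise AssertionError("edge count changed during rewiring")
    return result


def small_world_metrics(g: BinaryGraph, n_random: int = 100,
                        seed: int | None = None,
                        n_swaps_per_edge: int = 10) -> tuple[GlobalMetrics, NullEnsemble]:
    """Small-world summary of a connected graph against a rewired null ensemble."""
    if not g.is_connected():
        raise ValueError("small-world metrics require a connected graph")
    c = network_clustering(g)
    l = characteristic_path_length(g)
    ss = np.random.SeedSequence(seed)
    null_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_random)]
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    for i, s in enumerate(null_seeds):
        null = rewire_preserving_degree(g, n_swaps_per_edge, seed=s)
        c_rand[i] = network_clustering(null)
        l_rand[i] = characteristic_path_length(null)
    c_bar, l_bar = float(c_rand.mean()), float(l_rand.mean())
    gamma = c / c_bar
    lam = l / l_bar
    gm = GlobalMetrics(C=c, L=l, C_rand=c_bar, L_rand=l_bar,
                       gamma=gamma, lambda_=lam, sigma=gamma / lam)
    return gm, NullEnsemble(c_rand, l_rand, seed=seed if seed is not None else -1)
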