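"""Undirected binary graph container used throughout the network analysis.

A :class:`BinaryGraph` wraps a dense boolean adjacency matrix together with
its ordered node labels and the realized wiring cost (sparsity).  A dense
matrix is the right representation here: the networks are small (90 nodes)
and the metric code is dominated by matrix products and breadth-first
searches, both of which profit from contiguous arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["BinaryGraph"]


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph on an ordered node set.

    Attributes
    ----------
    adjacency
        Symmetric boolean (N, N) matrix with a zero diagonal.
    region_labels
        Node labels in matrix order.
    sparsity
        Realized wiring cost: edges / (N(N-1)/2).
    """

    adjacency: np.ndarray
    region_labels: tuple[str, ...] = ()
    sparsity: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        a = a.astype(bool)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        self.adjacency = a
        n = a.shape[0]
        if not self.region_labels:
            self.region_labels = tuple(f"n{i}" for i in range(n))
        else:
            self.region_labels = tuple(self.region_labels)
            if len(self.region_labels) != n:
                raise ValueError("label count must equal node count")
        if np.isnan(self.sparsity):
            pairs = n * (n - 1) // 2
            self.sparsity = self.n_edges / pairs if pairs else 0.0

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def edge_list(self) -> list[tuple[int, int]]:
        """Edges as (i, j) index pairs with i < j, in lexicographic order."""
        iu, ju = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(iu.tolist(), ju.tolist()))

    def neighbors(self, node: int) -> np.ndarray:
        return np.nonzero(self.adjacency[node])[0]

    def has_isolates(self) -> bool:
        return bool((self.adjacency.sum(axis=1) == 0).any())

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return True
        n_comp, _ = connected_components(
            csr_matrix(self.adjacency), directed=False
        )
        return n_comp == 1

    def component_sizes(self) -> np.ndarray:
        """Sizes of connected components, largest first."""
        if self.n_nodes == 0:
            return np.array([], dtype=np.int64)
        _, labels = connected_components(csr_matrix(self.adjacency), directed=False)
        return np.sort(np.bincount(labels))[::-1].astype(np.int64)

    def subgraph_without(self, nodes: Iterable[int]) -> "BinaryGraph":
        """Graph with the given node indices removed (labels preserved)."""
        drop = set(int(i) for i in nodes)
        keep = [i for i in range(self.n_nodes) if i not in drop]
        a = self.adjacency[np.ix_(keep, keep)]
        labels = tuple(self.region_labels[i] for i in keep)
        return BinaryGraph(a, labels)

    # -- interop -----------------------------------------------------------

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.adjacency.astype(int))
        mapping = {i: lab for i, lab in enumerate(self.region_labels)}
        return nx.relabel_nodes(g, mapping)

    @classmethod
    def from_networkx(cls, g, region_labels: Sequence[str] | None = None) -> "BinaryGraph":
        import networkx as nx

        nodes = list(g.nodes())
        a = nx.to_numpy_array(g, nodelist=nodes) > 0
        np.fill_diagonal(a, False)
        labels = tuple(region_labels) if region_labels else tuple(str(n) for n in nodes)
        return cls(a, labels)

    def copy(self) -> "BinaryGraph":
        return BinaryGraph(self.adjacency.copy(), self.region_labels, self.sparsity)
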