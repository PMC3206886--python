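"""Targeted-attack resilience of binary brain networks.

Nodes are removed in decreasing order of group-mean betweenness centrality
and the size of the largest connected component (as a fraction of the
original node count) is tracked after each removal.  A fragile network —
one whose integration depends on a few high-betweenness hubs — collapses
early; a resilient one degrades gracefully.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graph import BinaryGraph
from .metrics import betweenness

__all__ = [
    "RobustnessCurve",
    "attack_order",
    "targeted_attack",
    "compare_curves",
    "group_attack_analysis",
]


@dataclass
class RobustnessCurve:
    """Largest-connected-component decay under sequential node removal."""

    removed_fraction: np.ndarray
    lcc_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.removed_fraction = np.asarray(self.removed_fraction, dtype=float)
        self.lcc_fraction = np.asarray(self.lcc_fraction, dtype=float)
        if self.removed_fraction.shape != self.lcc_fraction.shape:
            raise ValueError("grid and curve lengths differ")
        if np.any(np.diff(self.lcc_fraction) > 1e-12):
            raise ValueError("lcc_fraction must be non-increasing")


def attack_order(betweenness_by_subject: np.ndarray,
                 region_labels=None) -> list[int]:
    """Node removal order: descending group-mean betweenness.

    ``betweenness_by_subject`` is a (subjects x nodes) matrix.  Ties break
    by canonical (ascending) label order, falling back to node index.
    """
    b = np.atleast_2d(np.asarray(betweenness_by_subject, dtype=float))
    if b.size == 0:
        raise ValueError("need at least one subject")
    mean_b = b.mean(axis=0)
    n = mean_b.shape[0]
    if region_labels is not None and len(region_labels) != n:
        raise ValueError("label count does not match node count")
    tiebreak = np.argsort(
        np.asarray(region_labels) if region_labels is not None else np.arange(n)
    )
    rank_of = np.empty(n, dtype=int)
    rank_of[tiebreak] = np.arange(n)
    order = sorted(range(n), key=lambda i: (-mean_b[i], rank_of[i]))
    return order


def targeted_attack(g: BinaryGraph, order, recompute: bool = False,
                    stop_at_singleton: bool = True) -> RobustnessCurve:
    """Remove nodes following ``order``, tracking LCC size / N after each step.

    The grid starts at zero removals (lcc_fraction 1.0 for a connected
    graph) and proceeds until every listed node is removed or the largest
    component has shrunk to a single node.  With ``recompute=True`` the
    order argument is ignored after the first removal and the highest-
    betweenness node of the current LCC is removed at each step instead.
    """
    n = g.n_nodes
    order = [int(i) for i in order]
    if any(i < 0 or i >= n for i in order):
        raise ValueError("attack order references a node outside the graph")
    if len(set(order)) != len(order):
        raise ValueError("attack order contains duplicate nodes")

    removed: list[int] = []
    fractions = [0.0]
    lcc = [g.component_sizes()[0] / n]
    current = g
    step = 0
    while True:
        if current.n_nodes == 0:
            break
        if stop_at_singleton and lcc[-1] * n <= 1:
            break
        if recompute:
            keep = [i for i in range(n) if i not in set(removed)]
            sub = g.subgraph_without(removed)
            b = _component_betweenness(sub)
            victim = keep[int(np.argmax(b))]
        else:
            if step >= len(order):
                break
            victim = order[step]
        removed.append(victim)
        step += 1
        current = g.subgraph_without(removed)
        fractions.append(len(removed) / n)
        sizes = current.component_sizes()
        lcc.append((sizes[0] if sizes.size else 0) / n)
    return RobustnessCurve(np.asarray(fractions), np.asarray(lcc))


def _component_betweenness(g: BinaryGraph) -> np.ndarray:
    """Betweenness computed within each connected component separately."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    if g.n_nodes == 0:
        return np.array([])
    _, labels = connected_components(csr_matrix(g.adjacency), directed=False)
    out = np.zeros(g.n_nodes)
    for comp in np.unique(labels):
        idx = np.nonzero(labels == comp)[0]
        if idx.size < 3:
            continue
        sub = BinaryGraph(g.adjacency[np.ix_(idx, idx)])
        out[idx] = betweenness(sub)
    return out


def compare_curves(group_a: list[RobustnessCurve],
                   group_b: list[RobustnessCurve],
                   alpha: float = 0.05,
                   method: str = "ttest",
                   n_permutations: int = 2000,
                   seed: int | None = None) -> pd.DataFrame:
    """Per-removal-step two-sample comparison of LCC fractions.

    All curves must share the removal grid.  ``method`` is ``'ttest'``
    (Welch two-sample t) or ``'permutation'`` (mean-difference permutation
    test).  The returned frame carries per-step p-values and a flag marking
    the contiguous significant range.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 subjects (no variance otherwise)")
    grid = group_a[0].removed_fraction
    for c in list(group_a) + list(group_b):
        if c.removed_fraction.shape != grid.shape or \
                not np.allclose(c.removed_fraction, grid):
            raise ValueError("curves must share a common removal grid")
    a = np.vstack([c.lcc_fraction for c in group_a])
    b = np.vstack([c.lcc_fraction for c in group_b])
    pvals = np.ones(grid.size)
    for j in range(grid.size):
        x, y = a[:, j], b[:, j]
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            # degenerate columns: identical -> no evidence, distinct -> certain
            pvals[j] = 1.0 if x[0] == y[0] else 0.0
            continue
        if method == "ttest":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pvals[j] = sps.ttest_ind(x, y, equal_var=False).pvalue
        elif method == "permutation":
            rng = np.random.default_rng(None if seed is None else seed + j)
            obs = abs(x.mean() - y.mean())
            pool = np.concatenate([x, y])
            count = 0
            for _ in range(n_permutations):
                rng.shuffle(pool)
                if abs(pool[: len(x)].mean() - pool[len(x):].mean()) >= obs - 1e-15:
                    count += 1
            pvals[j] = (count + 1) / (n_permutations + 1)
        else:
            raise ValueError("method must be 'ttest' or 'permutation'")
    sig = pvals < alpha
    # contiguous significant range: the longest run of significant steps
    in_range = np.zeros_like(sig)
    if sig.any():
        runs, start = [], None
        for j, s in enumerate(sig):
            if s and start is None:
                start = j
            elif not s and start is not None:
                runs.append((start, j)); start = None
        if start is not None:
            runs.append((start, sig.size))
        s0, s1 = max(runs, key=lambda r: r[1] - r[0])
        in_range[s0:s1] = True
    return pd.DataFrame({
        "removed_fraction": grid,
        "mean_lcc_a": a.mean(axis=0),
        "mean_lcc_b": b.mean(axis=0),
        "p": pvals,
        "significant": sig,
        "in_significant_range": in_range,
    })


def group_attack_analysis(graphs: dict[str, BinaryGraph],
                          betweenness_by_subject: np.ndarray,
                          subject_ids: list[str],
                          recompute: bool = False) -> dict[str, RobustnessCurve]:
    """Per-subject attack curves under one shared group-level node order."""
    labels = graphs[subject_ids[0]].region_labels
    order = attack_order(betweenness_by_subject, labels)
    return {s: targeted_attack(graphs[s], order, recompute=recompute,
                               stop_at_singleton=False)
            for s in subject_ids}
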