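"""Functional-connectivity matrix construction and sparsity thresholding.

A subject's regional time series become a symmetric Pearson correlation
matrix; binarizing the matrix at a fixed *sparsity* (wiring cost: realized
edges over all possible node pairs) keeps the strongest ``round(s*N(N-1)/2)``
correlations as edges, so all subjects' graphs carry the same edge count and
group comparisons are not confounded by connection density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graph import BinaryGraph
from .synthetic import RoiTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "correlation_matrix",
    "threshold_by_sparsity",
    "sweep_thresholds",
    "min_connected_sparsity",
    "fisher_z",
    "edge_group_stats",
    "parse_sparsity",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region Pearson correlation matrix."""

    r: np.ndarray
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        n = self.r.shape[0]
        if self.r.ndim != 2 or self.r.shape[1] != n:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        off = self.r[~np.eye(n, dtype=bool)]
        if off.size and (np.abs(off) > 1 + 1e-12).any():
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        self.r = (self.r + self.r.T) / 2
        np.fill_diagonal(self.r, 1.0)   # set, not computed
        self.region_labels = tuple(self.region_labels)
        if len(self.region_labels) != n:
            raise ValueError("label count must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


def correlation_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlations between all pairs of regional series."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for correlation")
    sd = ts.data.std(axis=1)
    constant = np.nonzero(sd == 0)[0]
    if constant.size:
        names = [ts.region_labels[i] for i in constant[:5]]
        raise ValueError(f"constant time series for region(s) {names}; "
                         "correlation undefined")
    r = np.corrcoef(ts.data)
    r = np.clip(r, -1.0, 1.0)
    return ConnectivityMatrix(r, ts.region_labels)


def _ranked_pairs(c: ConnectivityMatrix, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pair indices sorted by descending edge strength.

    Ties at equal strength break deterministically by lexicographic
    (row, col) order.
    """
    n = c.n_regions
    iu, ju = np.triu_indices(n, k=1)
    vals = c.r[iu, ju]
    key = np.abs(vals) if mode == "absolute" else vals
    # lexsort: last key is primary -> strength desc, then row asc, then col asc
    order = np.lexsort((ju, iu, -key))
    return iu[order], ju[order]


def threshold_by_sparsity(c: ConnectivityMatrix, sparsity: float,
                          mode: str = "signed") -> BinaryGraph:
    """Binarize a correlation matrix at a fixed wiring cost.

    Keeps the ``k = round(sparsity * N(N-1)/2)`` strongest pairs as edges
    (rounding half away from zero), ranking by signed correlation by default
    or by ``|r|`` when ``mode='absolute'``.  The diagonal is never eligible.
    """
    if not 0.0 < sparsity <= 1.0:
        raise ValueError(f"sparsity must lie in (0, 1], got {sparsity}")
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    n = c.n_regions
    max_edges = n * (n - 1) // 2
    k = int(np.floor(sparsity * max_edges + 0.5))
    if k < 1:
        raise ValueError(f"sparsity {sparsity} yields no edges for N={n}")
    iu, ju = _ranked_pairs(c, mode)
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[:k], ju[:k]] = True
    adj |= adj.T
    return BinaryGraph(adj, c.region_labels, sparsity=k / max_edges)


def sweep_thresholds(c: ConnectivityMatrix, low: float = 0.15,
                     high: float = 0.25, step: float = 0.01,
                     mode: str = "signed") -> list[BinaryGraph]:
    """Graphs at each sparsity of the inclusive grid ``low..high`` by ``step``.

    Because thresholding is rank selection, the edge set at a lower sparsity
    is nested inside the edge set at any higher sparsity.
    """
    if low > high:
        raise ValueError(f"low {low} exceeds high {high}")
    if step <= 0:
        raise ValueError("step must be positive")
    graphs = []
    s = low
    while s <= high + 1e-9:
        graphs.append(threshold_by_sparsity(c, round(s, 10), mode))
        s += step
    return graphs


def min_connected_sparsity(c: ConnectivityMatrix, candidates,
                           mode: str = "signed") -> float | None:
    """Smallest candidate sparsity giving a fully connected, isolate-free graph.

    Candidates are scanned in ascending order; returns ``None`` if no
    candidate qualifies.
    """
    cands = [float(s) for s in candidates]
    if not cands:
        raise ValueError("candidate list is empty")
    if sorted(cands) != cands:
        raise ValueError("candidates must be sorted ascending")
    for s in cands:
        g = threshold_by_sparsity(c, s, mode)
        if not g.has_isolates() and g.is_connected():
            return s
    return None


def fisher_z(r):
    """Fisher's variance-stabilizing transform, ``z = arctanh(r)``.

    Accepts scalars or arrays; requires ``|r| < 1``.
    """
    arr = np.asarray(r, dtype=float)
    if (np.abs(arr) >= 1.0).any():
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def edge_group_stats(matrices: dict[str, ConnectivityMatrix],
                     groups: dict[str, str], q: float = 0.05) -> pd.DataFrame:
    """Per-edge Fisher-z group comparison (patient vs control).

    For every region pair, correlations are Fisher-z transformed, group
    means computed, and a two-sample t-test run across subjects; p-values
    are Benjamini-Hochberg adjusted over all pairs.
    """
    from statsmodels.stats.multitest import multipletests

    ids = list(matrices)
    labels = matrices[ids[0]].region_labels
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    z = np.vstack([
        np.arctanh(np.clip(matrices[s].r[iu, ju], -0.999999, 0.999999))
        for s in ids
    ])
    grp = np.asarray([groups[s] for s in ids])
    z_pat, z_con = z[grp == "patient"], z[grp == "control"]
    if len(z_pat) < 2 or len(z_con) < 2:
        raise ValueError("need >= 2 subjects per group for edge statistics")
    t, p = sps.ttest_ind(z_pat, z_con, axis=0)
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame({
        "region_a": [labels[i] for i in iu],
        "region_b": [labels[j] for j in ju],
        "z_mean_patient": z_pat.mean(axis=0),
        "z_mean_control": z_con.mean(axis=0),
        "t": t,
        "p": p,
        "p_fdr": p_adj,
        "significant": p_adj < q,
    })


def parse_sparsity(text) -> float:
    """Parse '15%' or '0.15' (or a number) to a fraction in (0, 1]."""
    if isinstance(text, (int, float)):
        val = float(text)
    else:
        text = str(text).strip()
        if text.endswith("%"):
            val = float(text[:-1]) / 100.0
        else:
            val = float(text)
            if val > 1.0:
                val /= 100.0
    if not 0.0 < val <= 1.0:
        raise ValueError(f"sparsity {text!r} out of range (0, 1]")
    return val
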