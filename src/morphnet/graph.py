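"""Graph topology: clustering, path length, nodal efficiency, and
degree-preserving null-model normalization.

All metrics operate on simple, undirected, binary adjacency matrices
(numpy bool/0-1 arrays); shortest paths come from
:func:`scipy.sparse.csgraph.shortest_path` (unweighted BFS).  Small-world
normalization divides the observed clustering coefficient and
characteristic path length by their means over an ensemble of
Maslov-Sneppen rewired null networks that preserve the exact degree
sequence and connectivity.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "DisconnectedGraphError",
    "clustering_coefficient",
    "local_clustering",
    "characteristic_path_length",
    "distance_matrix",
    "nodal_efficiency",
    "rewire_null",
    "normalize_small_world",
    "auc_over_sparsity",
]

logger = logging.getLogger(__name__)


class DisconnectedGraphError(ValueError):
    """A path-based metric was requested on a disconnected graph."""


def _as_adjacency(adj) -> np.ndarray:
    A = np.asarray(adj)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    A = A.astype(bool)
    if np.any(A != A.T):
        raise ValueError("adjacency must be symmetric (undirected graph)")
    if np.any(np.diag(A)):
        raise ValueError("adjacency must have a zero diagonal (simple graph)")
    return A


def local_clustering(adj) -> np.ndarray:
    """Per-node clustering ``2 t_i / (k_i (k_i - 1))``; degree < 2 gives 0."""
    A = _as_adjacency(adj).astype(float)
    k = A.sum(axis=1)
    # t_i = number of triangles through node i = (A^3)_ii / 2
    t = ((A @ A) * A).sum(axis=1) / 2.0
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return c


def clustering_coefficient(adj) -> float:
    """Watts-Strogatz average clustering coefficient (Cp)."""
    return float(np.mean(local_clustering(adj)))


def distance_matrix(adj) -> np.ndarray:
    """All-pairs unweighted shortest-path distances (inf if unreachable)."""
    A = _as_adjacency(adj)
    return shortest_path(csr_matrix(A.astype(np.int8)), method="D", unweighted=True)


def characteristic_path_length(adj) -> float:
    """Mean shortest-path length over unordered node pairs (Lp)."""
    D = distance_matrix(adj)
    n = D.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    off = D[np.triu_indices(n, 1)]
    if np.any(np.isinf(off)):
        raise DisconnectedGraphError("characteristic path length of a disconnected graph")
    return float(off.mean())


def nodal_efficiency(adj, node: int | None = None):
    """Nodal efficiency ``E_i = mean over j != i of 1 / d_ij``.

    Returns the full vector when ``node`` is None, else a scalar.  Equals
    1 exactly when the node is adjacent to every other node.
    """
    D = distance_matrix(adj)
    n = D.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 nodes")
    if np.any(np.isinf(D)):
        raise DisconnectedGraphError("nodal efficiency of a disconnected graph")
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    E = inv.sum(axis=1) / (n - 1)
    if node is None:
        return E
    return float(E[int(node)])


def _reachable(nbrs, a: int, b: int) -> bool:
    """Depth-first reachability of ``b`` from ``a`` with early exit."""
    seen = {a}
    stack = [a]
    while stack:
        u = stack.pop()
        for w in nbrs[u]:
            if w == b:
                return True
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def rewire_null(adj, n_swaps: int | None = None, seed=None, rng=None) -> np.ndarray:
    """Maslov-Sneppen degree-preserving randomization of a connected graph.

    Repeated double-edge swaps ``(a-b, c-d) -> (a-d, c-b)`` that keep the
    graph simple.  Swaps that would disconnect the graph are rejected: a
    swap of a connected graph leaves it connected iff ``b`` remains
    reachable from ``a`` afterwards (every node stays attached to one of
    the four endpoints), which is checked with an early-exit search.
    ``n_swaps`` counts attempts (default ``10 * |E|``, a standard mixing
    heuristic).  Graphs admitting no valid swap (e.g. complete graphs)
    are returned unchanged with a logged notice.
    """
    A = _as_adjacency(adj).copy()
    iu, ju = np.triu_indices(A.shape[0], 1)
    mask = A[iu, ju]
    edges = [(int(i), int(j)) for i, j in zip(iu[mask], ju[mask])]
    n_edges = len(edges)
    if n_edges < 2:
        logger.info("graph with %d edges admits no double-edge swap", n_edges)
        return A
    if n_swaps is None:
        n_swaps = 10 * n_edges
    if rng is None:
        rng = np.random.default_rng(seed)
    nbrs = [set(np.flatnonzero(A[i]).tolist()) for i in range(A.shape[0])]

    picks = rng.integers(0, n_edges, size=(n_swaps, 2))
    flips = rng.integers(0, 2, size=(n_swaps, 2))
    performed = 0
    for (e1, e2), (f1, f2) in zip(picks, flips):
        if e1 == e2:
            continue
        a, b = edges[e1]
        if f1:
            a, b = b, a
        c, d = edges[e2]
        if f2:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if d in nbrs[a] or b in nbrs[c]:
            continue
        # perform swap
        nbrs[a].remove(b); nbrs[b].remove(a)
        nbrs[c].remove(d); nbrs[d].remove(c)
        nbrs[a].add(d); nbrs[d].add(a)
        nbrs[c].add(b); nbrs[b].add(c)
        if _reachable(nbrs, a, b):
            edges[e1] = (a, d) if a < d else (d, a)
            edges[e2] = (c, b) if c < b else (b, c)
            performed += 1
        else:  # disconnecting swap: revert
            nbrs[a].remove(d); nbrs[d].remove(a)
            nbrs[c].remove(b); nbrs[b].remove(c)
            nbrs[a].add(b); nbrs[b].add(a)
            nbrs[c].add(d); nbrs[d].add(c)
    if performed == 0:
        logger.info("no valid double-edge swap found; graph returned unchanged")
        return A
    out = np.zeros_like(A)
    for i, js in enumerate(nbrs):
        for j in js:
            out[i, j] = True
    return out


def normalize_small_world(
    adj,
    n_null: int = 100,
    seed=None,
    mode: str = "ratio",
    n_swaps: int | None = None,
):
    """Clustering and path length normalized against rewired null networks.

    Returns ``(zCp, zLp)``.  The default ``mode="ratio"`` divides the
    observed value by the mean over ``n_null`` degree-matched rewired
    networks (the gamma/lambda small-world convention); ``mode="zscore"``
    standardizes by the null mean and standard deviation instead.
    """
    if mode not in ("ratio", "zscore"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    A = _as_adjacency(adj)
    cp = clustering_coefficient(A)
    lp = characteristic_path_length(A)
    children = np.random.SeedSequence(seed).spawn(n_null)
    null_cp = np.empty(n_null)
    null_lp = np.empty(n_null)
    for k, child in enumerate(children):
        null = rewire_null(A, n_swaps=n_swaps, rng=np.random.default_rng(child))
        null_cp[k] = clustering_coefficient(null)
        null_lp[k] = characteristic_path_length(null)
    if mode == "zscore":
        return (
            float((cp - null_cp.mean()) / null_cp.std(ddof=1)),
            float((lp - null_lp.mean()) / null_lp.std(ddof=1)),
        )
    mean_cp = null_cp.mean()
    if mean_cp == 0.0:
        raise ValueError(
            "mean null clustering coefficient is zero; use denser sparsity levels"
        )
    return float(cp / mean_cp), float(lp / null_lp.mean())


def auc_over_sparsity(values, grid) -> float:
    """Trapezoidal integral of per-level values over the sparsity grid,
    divided by the grid span (a range-normalized mean); a single-level
    grid returns the value itself."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(grid, dtype=float)
    if v.shape != g.shape:
        raise ValueError("values and grid must have equal length")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite metric values")
    if np.any(np.diff(g) <= 0):
        raise ValueError("sparsity grid must be strictly increasing")
    if g.size == 1:
        return float(v[0])
    return float(np.trapezoid(v, g) / (g[-1] - g[0]))
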