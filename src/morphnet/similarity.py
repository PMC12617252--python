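"""Morphological similarity networks and sparsity thresholding.

Each subject and feature yields a symmetric n_roi x n_roi similarity
matrix whose entry (i, j) is ``1 - JSD(p_i, p_j)``: the base-2
Jensen-Shannon divergence between the two regions' vertex-value
distributions, subtracted from one so that larger weights mean more
similar morphology.  The matrix is binarized over a grid of sparsity
levels; the maximum-weight spanning tree is forced into every level so
each thresholded graph stays connected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .features import RoiDensity, VertexFeatureMap, MissingRegionError, \
    kernel_mass, silverman_bandwidth

__all__ = [
    "SimilarityMatrix",
    "GraphEnsemble",
    "GridMismatchError",
    "jsd",
    "build_similarity",
    "threshold_ensemble",
    "default_sparsity_grid",
    "round_half_away",
    "maximum_spanning_edges",
]

#: floor applied to probability cells before any logarithm (perturbs JSD
#: by < 1e-9 while avoiding 0*log 0)
_EPS = 1e-12


class GridMismatchError(ValueError):
    """Two densities were compared on different evaluation grids."""


def default_sparsity_grid() -> np.ndarray:
    """Sparsity levels 0.03, 0.04, ..., 0.30 (28 levels)."""
    return np.round(np.arange(3, 31) * 0.01, 2)


def round_half_away(x: float) -> int:
    """Round half away from zero (platform-stable edge counts)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _jsd_mass(p: np.ndarray, q: np.ndarray) -> float:
    p = np.maximum(p, _EPS)
    p = p / p.sum()
    q = np.maximum(q, _EPS)
    q = q / q.sum()
    m = 0.5 * (p + q)
    val = 0.5 * np.sum(p * np.log2(p / m)) + 0.5 * np.sum(q * np.log2(q / m))
    return float(min(max(val, 0.0), 1.0))


def jsd(p, q) -> float:
    """Base-2 Jensen-Shannon divergence between two discrete distributions.

    ``JSD(p, q) = KL(p||m)/2 + KL(q||m)/2`` with ``m = (p+q)/2``; with
    base-2 logarithms the value lies in [0, 1], is symmetric, and is zero
    iff ``p == q`` (up to the 1e-12 cell floor).  Accepts probability
    vectors or :class:`RoiDensity` objects; densities must share a grid.
    """
    if isinstance(p, RoiDensity) and isinstance(q, RoiDensity):
        if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
            raise GridMismatchError("densities are defined on different grids")
        p, q = p.mass, q.mass
    elif isinstance(p, RoiDensity) or isinstance(q, RoiDensity):
        raise GridMismatchError("compare two RoiDensity objects or two vectors")
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise GridMismatchError("distributions have different lengths")
    return _jsd_mass(p, q)


@dataclass
class SimilarityMatrix:
    """Symmetric edge-weight matrix of one subject x feature network."""

    subject_id: str
    feature: str
    weights: np.ndarray
    roi_ids: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids, dtype=int)
        W = self.weights
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if np.any(~np.isfinite(W)):
            raise ValueError("similarity matrix contains non-finite entries")
        if np.max(np.abs(W - W.T)) > 1e-12:
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def build_similarity(
    vmap: VertexFeatureMap,
    grid_size: int = 28,
    bandwidth="silverman",
    variant: str = "one_minus_jsd",
    grid_policy: str = "pair_union",
    roi_ids=None,
) -> SimilarityMatrix:
    """Similarity matrix ``w_ij = 1 - JSD(p_i, p_j)`` over all ROI pairs.

    ``grid_policy`` controls the common support on which two regions'
    densities are compared:

    * ``"pair_union"`` (default): for each ROI pair, both densities are
      evaluated on a fresh grid spanning the union of the two value
      ranges — JSD requires a shared support, and the pairwise union is
      the tightest one.
    * ``"subject_global"``: one grid spanning the subject's full value
      range for the feature; cheaper, kept as a sensitivity switch.

    ``variant="one_minus_sqrt_jsd"`` uses the metric square root of the
    divergence instead.
    """
    if variant not in ("one_minus_jsd", "one_minus_sqrt_jsd"):
        raise ValueError(f"unknown similarity variant {variant!r}")
    if grid_policy not in ("pair_union", "subject_global"):
        raise ValueError(f"unknown grid policy {grid_policy!r}")

    ids = vmap.roi_ids if roi_ids is None else np.asarray(roi_ids, int)
    present = set(vmap.roi_ids.tolist())
    missing = [int(r) for r in ids if int(r) not in present]
    if missing:
        raise MissingRegionError(
            f"ROIs with no vertices in {vmap.subject_id}/{vmap.feature}: {missing}"
        )
    n = len(ids)
    vals = [vmap.roi_values(r) for r in ids]
    if bandwidth == "silverman":
        hs = [silverman_bandwidth(v) for v in vals]
    else:
        h = float(bandwidth)
        hs = [h if np.ptp(v) > 0 else 0.0 for v in vals]
    lows = np.array([v.min() for v in vals])
    highs = np.array([v.max() for v in vals])

    D = np.zeros((n, n))
    if grid_policy == "subject_global":
        lo, hi = float(lows.min()), float(highs.max())
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        grid = np.linspace(lo, hi, grid_size)
        P = np.stack([kernel_mass(v, h, grid) for v, h in zip(vals, hs)])
        for i in range(n - 1):
            p = P[i]
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = _jsd_mass(p, P[j])
    else:
        unit = np.linspace(0.0, 1.0, grid_size)
        for i in range(n - 1):
            vi, hi_bw = vals[i], hs[i]
            for j in range(i + 1, n):
                lo = min(lows[i], lows[j])
                hi = max(highs[i], highs[j])
                if hi <= lo:  # both regions constant at the same value
                    if vals[j][0] == vi[0]:
                        continue  # identical -> divergence 0
                    lo, hi = lo - 0.5, hi + 0.5
                grid = lo + (hi - lo) * unit
                p = kernel_mass(vi, hi_bw, grid)
                q = kernel_mass(vals[j], hs[j], grid)
                D[i, j] = D[j, i] = _jsd_mass(p, q)

    if variant == "one_minus_sqrt_jsd":
        W = 1.0 - np.sqrt(D)
    else:
        W = 1.0 - D
    np.fill_diagonal(W, 1.0)
    return SimilarityMatrix(vmap.subject_id, vmap.feature, W, ids)


@dataclass
class GraphEnsemble:
    """Binary adjacencies of one network across an ordered sparsity grid.

    Edge sets are nested along the grid and every adjacency is connected
    (the spanning-tree backbone is present at every level).
    """

    subject_id: str
    feature: str
    sparsities: np.ndarray
    adjacencies: list

    def __post_init__(self) -> None:
        self.sparsities = np.asarray(self.sparsities, dtype=float)
        if np.any(self.sparsities <= 0) or np.any(self.sparsities > 1):
            raise ValueError("sparsity levels must lie in (0, 1]")
        if np.any(np.diff(self.sparsities) <= 0):
            raise ValueError("sparsity grid must be strictly increasing")

    def adjacency(self, sparsity: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.sparsities - sparsity)))
        if abs(self.sparsities[idx] - sparsity) > 1e-9:
            raise KeyError(f"sparsity {sparsity} not in ensemble grid")
        return self.adjacencies[idx]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _ranked_edges(W: np.ndarray):
    """All upper-triangular edges ranked: maximum-weight spanning-tree edges
    first (in Kruskal acceptance order), then the rest by descending weight;
    ties broken by lexicographic (i, j)."""
    n = W.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = W[iu, ju]
    order = np.lexsort((ju, iu, -w))
    uf = _UnionFind(n)
    mst, rest = [], []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            mst.append((i, j))
        else:
            rest.append((i, j))
    if len(mst) != n - 1:
        raise ValueError("similarity graph is not connected; cannot build a spanning tree")
    return mst, rest


def maximum_spanning_edges(W: np.ndarray):
    """Edges of the maximum-weight spanning tree of a symmetric weight matrix
    (equivalently, the minimum spanning tree of ``1 - W``); deterministic
    lexicographic tie-breaking."""
    return _ranked_edges(np.asarray(W, float))[0]


def threshold_ensemble(S: SimilarityMatrix, sparsity_grid=None) -> GraphEnsemble:
    """Binarize a similarity matrix over a sparsity grid with a spanning-tree
    backbone.

    At sparsity ``s`` the graph keeps ``max(n - 1, round(s * n(n-1)/2))``
    edges: the maximum-weight spanning tree plus the strongest remaining
    edges, so every level is connected and edge sets are nested along the
    grid.
    """
    grid = default_sparsity_grid() if sparsity_grid is None else np.asarray(sparsity_grid, float)
    W = S.weights
    n = W.shape[0]
    total = n * (n - 1) // 2
    mst, rest = _ranked_edges(W)
    ranked = mst + rest

    adjacencies = []
    counts = []
    for s in grid:
        k = max(n - 1, round_half_away(float(s) * total))
        counts.append(min(k, total))
    A = np.zeros((n, n), dtype=bool)
    filled = 0
    for k in counts:
        while filled < k:
            i, j = ranked[filled]
            A[i, j] = A[j, i] = True
            filled += 1
        adjacencies.append(A.copy())
    return GraphEnsemble(S.subject_id, S.feature, grid, adjacencies)
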