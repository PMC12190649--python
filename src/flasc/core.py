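"""Density backbone: core distances, mutual reachability, exact MST, single linkage.

The backbone models density through the distance to the ``k``-th nearest
neighbour (self-inclusive): the density estimate at a point is the reciprocal
of that *core distance*.  Pairwise distances are smoothed into *mutual
reachability* distances, ``max(kappa_i, kappa_j, d_ij)``, which push sparse
points apart and make single-linkage clustering on the resulting minimum
spanning tree equivalent to tracking connected components of density
superlevel sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import pairwise_distances


def validate_points(X) -> np.ndarray:
    """Validate a point cloud: an N x D matrix of finite reals, N, D >= 1."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D point matrix, got ndim={X.ndim}")
    if X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError(f"need at least one point and one feature, got shape {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("point cloud contains non-finite values")
    return X


def distance_matrix(X: np.ndarray, metric: str | callable = "euclidean") -> np.ndarray:
    """Dense symmetric pairwise distance matrix with an exactly zero diagonal.

    ``metric`` is a plug-in contract: any metric name understood by
    scikit-learn, or a callable ``f(x, y) -> float``.
    """
    D = pairwise_distances(X, metric=metric)
    np.fill_diagonal(D, 0.0)
    return D


@dataclass(frozen=True)
class CoreDistanceTable:
    """Per-point core distances ``kappa`` for a fixed neighbour count ``k``.

    The ordering is self-inclusive: a point is its own first neighbour, so
    ``k=1`` yields all-zero core distances.  ``density`` is ``1/kappa`` with
    ``+inf`` where ``kappa == 0`` (duplicate points).
    """

    k: int
    kappa: np.ndarray

    @property
    def density(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(self.kappa > 0, 1.0 / np.where(self.kappa > 0, self.kappa, 1.0), np.inf)


def compute_core_distances(
    X: np.ndarray,
    k: int,
    metric: str | callable = "euclidean",
    dists: np.ndarray | None = None,
) -> CoreDistanceTable:
    """Distance from each point to its ``k``-th nearest neighbour (self-inclusive).

    Parameters
    ----------
    X : array of shape (n, d)
    k : int
        Neighbour count, ``1 <= k <= n``; acts as the density smoothing factor.
    dists : optional precomputed dense distance matrix.
    """
    X = validate_points(X)
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")
    if dists is None:
        dists = distance_matrix(X, metric)
    kappa = np.partition(dists, k - 1, axis=1)[:, k - 1]
    return CoreDistanceTable(k=k, kappa=np.ascontiguousarray(kappa))


def mutual_reachability_matrix(dists: np.ndarray, cores: CoreDistanceTable) -> np.ndarray:
    """Dense mutual reachability matrix ``max(kappa_i, kappa_j, d_ij)``, zero diagonal."""
    kappa = cores.kappa
    M = np.maximum(dists, np.maximum(kappa[:, None], kappa[None, :]))
    np.fill_diagonal(M, 0.0)
    return M


def mutual_reachability(i: int, j: int, dists: np.ndarray, cores: CoreDistanceTable) -> float:
    """Mutual reachability between two points; 0 when ``i == j``."""
    n = dists.shape[0]
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"point index out of range for n={n}")
    if i == j:
        return 0.0
    return float(max(dists[i, j], cores.kappa[i], cores.kappa[j]))


@dataclass
class EdgeList:
    """A weighted edge list with ``u < v`` per edge (mutual-reachability weights)."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.intp)
        self.v = np.asarray(self.v, dtype=np.intp)
        self.w = np.asarray(self.w, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.w)

    @property
    def total_weight(self) -> float:
        return float(self.w.sum())


def build_mst(
    X: np.ndarray | None,
    cores: CoreDistanceTable,
    metric: str | callable = "euclidean",
    mreach: np.ndarray | None = None,
) -> EdgeList:
    """Exact minimum spanning tree of the complete mutual-reachability graph.

    Dense Prim's algorithm; ties are resolved deterministically (lowest vertex
    index wins at every argmin, and the earliest-seen source is kept on equal
    candidate weights).  Edges are returned sorted by ``(w, u, v)``.
    """
    if mreach is None:
        X = validate_points(X)
        dists = distance_matrix(X, metric)
        mreach = mutual_reachability_matrix(dists, cores)
    n = mreach.shape[0]
    if n == 0:
        raise ValueError("cannot build an MST of an empty point cloud")
    if n == 1:
        return EdgeList(np.empty(0, np.intp), np.empty(0, np.intp), np.empty(0))

    in_tree = np.zeros(n, dtype=bool)
    best = mreach[0].copy()
    best[0] = np.inf
    src = np.zeros(n, dtype=np.intp)
    in_tree[0] = True

    us = np.empty(n - 1, dtype=np.intp)
    vs = np.empty(n - 1, dtype=np.intp)
    ws = np.empty(n - 1, dtype=np.float64)
    for t in range(n - 1):
        j = int(np.argmin(best))
        s = src[j]
        us[t], vs[t] = (s, j) if s < j else (j, s)
        ws[t] = best[j]
        in_tree[j] = True
        best[j] = np.inf
        row = mreach[j]
        upd = ~in_tree & (row < best)
        best[upd] = row[upd]
        src[upd] = j

    order = np.lexsort((vs, us, ws))
    return EdgeList(us[order], vs[order], ws[order])


@dataclass
class Dendrogram:
    """Single-linkage merge sequence in scipy ``linkage`` node convention.

    Merge ``t`` joins nodes ``left[t]`` and ``right[t]`` (ids ``< n`` are
    points, ``n + s`` is merge ``s``) at ``height[t]``, producing a node of
    ``size[t]`` points.  Heights are non-decreasing along the sequence.
    """

    left: np.ndarray
    right: np.ndarray
    height: np.ndarray
    size: np.ndarray
    n_points: int

    def __len__(self) -> int:
        return len(self.height)


class UnionFind:
    """Array-based union-find with union by rank and path compression."""

    __slots__ = ("parent", "rank")

    def __init__(self, n: int):
        self.parent = np.arange(n, dtype=np.intp)
        self.rank = np.zeros(n, dtype=np.intp)

    def find(self, x: int) -> int:
        parent = self.parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, x: int, y: int) -> int:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return rx
        if self.rank[rx] < self.rank[ry]:
            rx, ry = ry, rx
        self.parent[ry] = rx
        if self.rank[rx] == self.rank[ry]:
            self.rank[rx] += 1
        return rx


def single_linkage(mst: EdgeList, n: int) -> Dendrogram:
    """Single-linkage dendrogram from a spanning tree via union-find.

    Edges are processed in non-decreasing weight with lexicographic
    tie-breaks, so repeated runs on equal-weight input are identical.
    """
    if len(mst) != n - 1 and n > 0:
        raise ValueError(
            f"input is not a spanning tree on {n} points: expected {n - 1} edges, got {len(mst)}"
        )
    order = np.lexsort((mst.v, mst.u, mst.w))
    uf = UnionFind(n)
    node_of = np.arange(n, dtype=np.intp)
    size_of = np.ones(n, dtype=np.intp)

    left = np.empty(max(n - 1, 0), dtype=np.intp)
    right = np.empty(max(n - 1, 0), dtype=np.intp)
    height = np.empty(max(n - 1, 0), dtype=np.float64)
    size = np.empty(max(n - 1, 0), dtype=np.intp)
    for t, e in enumerate(order):
        ru, rv = uf.find(int(mst.u[e])), uf.find(int(mst.v[e]))
        if ru == rv:
            raise ValueError("input edge list contains a cycle; not a spanning tree")
        a, b = node_of[ru], node_of[rv]
        left[t], right[t] = (a, b) if a < b else (b, a)
        height[t] = mst.w[e]
        merged = size_of[ru] + size_of[rv]
        size[t] = merged
        r = uf.union(ru, rv)
        node_of[r] = n + t
        size_of[r] = merged
    return Dendrogram(left=left, right=right, height=height, size=size, n_points=n)
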