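"""Within-cluster branch (flare) detection.

For every selected density cluster the distance to the cluster's
membership-weighted centroid defines an *eccentricity* field.  Maximal
connected subsets of points above an eccentricity threshold correspond to
branches of the cluster's shape; lowering the threshold merges them towards
the centre.  Connectivity is supplied by a *cluster approximation graph*
(the full variant keeps all member pairs within the longest cluster-MST
mutual reachability; the core variant keeps the cluster-restricted k-NN
edges plus the MST).  Condensing the resulting join tree under a minimum
branch size, selecting segments, and labelling late-joining points as the
cluster centre yields the flat branch labelling combined with the cluster
labelling into the final result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .core import CoreDistanceTable, EdgeList, validate_points
from .hierarchy import (
    SUPERLEVEL,
    CondensedTree,
    SelectionResult,
    _condense_union,
    _select,
    simplify_persistence,
)


@dataclass
class ClusterView:
    """One selected density cluster: members, their cluster-membership
    probabilities, the probability-weighted centroid, the cluster-restricted
    MST (local vertex indices) and its largest edge weight ``d_max``."""

    members: np.ndarray
    probabilities: np.ndarray
    centroid: np.ndarray
    mst: EdgeList
    d_max: float

    @property
    def n_members(self) -> int:
        return len(self.members)


def cluster_centroid(points: np.ndarray, probabilities: np.ndarray) -> np.ndarray:
    """Probability-weighted mean of member coordinates (uniform if all zero)."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points.reshape(-1, 1)
    if len(points) == 0:
        raise ValueError("cannot compute the centroid of an empty cluster")
    w = np.asarray(probabilities, dtype=np.float64)
    if w.sum() <= 0:
        w = np.ones(len(points))
    return np.average(points, axis=0, weights=w)


def eccentricity(
    points: np.ndarray, centroid: np.ndarray, metric: str | callable = "euclidean"
) -> np.ndarray:
    """Distance of each member to the cluster centroid."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points.reshape(-1, 1)
    if callable(metric):
        return np.array([float(metric(centroid, p)) for p in points])
    if metric != "euclidean":
        from sklearn.metrics import pairwise_distances

        return pairwise_distances(centroid.reshape(1, -1), points, metric=metric)[0]
    return np.linalg.norm(points - centroid[None, :], axis=1)


def build_cluster_view(
    X: np.ndarray,
    members: np.ndarray,
    probabilities: np.ndarray,
    global_mst: EdgeList,
) -> ClusterView:
    """Restrict the global MST to a cluster's members.

    Cluster members always form a connected subtree of the global MST (they
    are a connected component at the filtration scale where the cluster is
    born), so the restriction is a spanning tree of the members.
    """
    members = np.asarray(members, dtype=np.intp)
    if len(members) == 0:
        raise ValueError("empty cluster")
    local = -np.ones(X.shape[0], dtype=np.intp)
    local[members] = np.arange(len(members))
    inside = (local[global_mst.u] >= 0) & (local[global_mst.v] >= 0)
    mst = EdgeList(
        local[global_mst.u[inside]], local[global_mst.v[inside]], global_mst.w[inside]
    )
    if len(mst) != len(members) - 1:
        raise ValueError("cluster members do not induce a subtree of the global MST")
    centroid = cluster_centroid(X[members], probabilities)
    d_max = float(mst.w.max()) if len(mst) else 0.0
    return ClusterView(
        members=members,
        probabilities=np.asarray(probabilities, dtype=np.float64),
        centroid=centroid,
        mst=mst,
        d_max=d_max,
    )


@dataclass
class ApproximationGraph:
    """Per-cluster connectivity graph.

    Vertices are local member indices; every edge carries its mutual
    reachability ``w`` and the filtration value ``f = min(e_u, e_v)``, the
    eccentricity of its least eccentric endpoint.
    """

    variant: str
    members: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    f: np.ndarray

    @property
    def n_vertices(self) -> int:
        return len(self.members)

    def __len__(self) -> int:
        return len(self.w)

    def adjacency(self) -> csr_matrix:
        n = self.n_vertices
        return csr_matrix(
            (np.concatenate([self.w, self.w]),
             (np.concatenate([self.u, self.v]), np.concatenate([self.v, self.u]))),
            shape=(n, n),
        )

    def is_connected(self) -> bool:
        if self.n_vertices == 1:
            return True
        return connected_components(self.adjacency(), directed=False)[0] == 1


def _finish_graph(variant, members, keep, sub_mreach, mst, ecc):
    iu, iv = np.triu_indices(len(members), k=1)
    mask = keep[iu, iv]
    u, v = iu[mask], iv[mask]
    w = sub_mreach[u, v]
    # guarantee the MST edges are present
    have = set(zip(u.tolist(), v.tolist()))
    extra_u, extra_v, extra_w = [], [], []
    for a, b, wt in zip(mst.u, mst.v, mst.w):
        a, b = (int(a), int(b)) if a < b else (int(b), int(a))
        if (a, b) not in have:
            extra_u.append(a)
            extra_v.append(b)
            extra_w.append(float(wt))
    if extra_u:
        u = np.concatenate([u, extra_u]).astype(np.intp)
        v = np.concatenate([v, extra_v]).astype(np.intp)
        w = np.concatenate([w, extra_w])
    f = np.minimum(ecc[u], ecc[v])
    order = np.lexsort((v, u))
    return ApproximationGraph(
        variant=variant, members=members, u=u[order], v=v[order], w=w[order], f=f[order]
    )


def extract_full_graph(
    cluster: ClusterView,
    dists: np.ndarray,
    cores: CoreDistanceTable,
    ecc: np.ndarray,
) -> ApproximationGraph:
    """All member pairs whose mutual reachability is at most ``d_max``, the
    longest cluster-MST edge; the cluster MST is a subset by construction."""
    m = cluster.members
    kap = cores.kappa[m]
    sub = np.maximum(dists[np.ix_(m, m)], np.maximum(kap[:, None], kap[None, :]))
    np.fill_diagonal(sub, 0.0)
    keep = sub <= cluster.d_max
    return _finish_graph("full", m, keep, sub, cluster.mst, ecc)


def extract_core_graph(
    cluster: ClusterView,
    dists: np.ndarray,
    cores: CoreDistanceTable,
    ecc: np.ndarray,
) -> ApproximationGraph:
    """Cluster MST plus all member pairs within each other's core distance
    (the cluster-restricted k-nearest-neighbour graph union the MST)."""
    m = cluster.members
    kap = cores.kappa[m]
    subd = dists[np.ix_(m, m)]
    sub = np.maximum(subd, np.maximum(kap[:, None], kap[None, :]))
    np.fill_diagonal(sub, 0.0)
    keep = subd <= np.maximum(kap[:, None], kap[None, :])
    return _finish_graph("core", m, keep, sub, cluster.mst, ecc)


def branch_condensed_tree(
    graph: ApproximationGraph, ecc: np.ndarray, min_branch_size: int
) -> CondensedTree:
    """Join tree of the eccentricity superlevel filtration, condensed.

    Vertices enter at their eccentricity and edges at the eccentricity of
    their least eccentric endpoint, processed in decreasing order; the
    condensed tree records branch births (tips), merges, and the values at
    which individual points join (their exit records)."""
    n = graph.n_vertices
    if n == 1:
        t = _condense_union(
            np.empty(0, np.intp), np.empty(0, np.intp), np.empty(0), 1,
            min_branch_size, SUPERLEVEL,
        )
        t.value[:] = ecc[0]
        return t
    try:
        return _condense_union(graph.u, graph.v, graph.f, n, min_branch_size, SUPERLEVEL)
    except ValueError as err:
        raise ValueError(f"approximation graph is disconnected: {err}") from err


@dataclass
class BranchResult:
    """Branch labelling of one cluster.

    ``labels`` are local sub-labels: branches ``0..B-1`` then, when present,
    the centre label ``B`` for points that enter the eccentricity filtration
    only after the selected branches have connected.
    """

    labels: np.ndarray
    probabilities: np.ndarray
    selected: np.ndarray
    persistences: np.ndarray
    roots: np.ndarray          # global point indices, one per branch
    centroids: np.ndarray      # per-branch weighted centroids
    has_centre: bool
    tree: CondensedTree = field(repr=False, default=None)
    graph: ApproximationGraph = field(repr=False, default=None)

    @property
    def n_branches(self) -> int:
        return len(self.selected)

    @property
    def centre_label(self) -> int | None:
        return self.n_branches if self.has_centre else None


def _branches_from_graph(
    graph: ApproximationGraph,
    ecc: np.ndarray,
    X: np.ndarray,
    min_branch_size: int = 10,
    selection_method: str = "eom",
    selection_persistence: float = 0.0,
) -> BranchResult:
    tree = branch_condensed_tree(graph, ecc, min_branch_size)
    if selection_persistence > 0:
        tree = simplify_persistence(tree, selection_persistence)
    sel = _select(
        tree,
        method=selection_method,
        allow_single=True,
        selection_epsilon=0.0,
        zero_label_single=True,
    )
    labels = sel.labels.copy()
    probabilities = sel.probabilities.copy()
    n_branches = sel.n_clusters

    noise = labels < 0
    has_centre = bool(noise.any())
    if has_centre:
        labels[noise] = n_branches
        births = tree.births()
        e_merge = min(births[int(s)] for s in sel.selected)
        if e_merge > 0:
            probabilities[noise] = np.clip(1.0 - ecc[noise] / e_merge, 0.0, 1.0)
        else:
            probabilities[noise] = np.where(ecc[noise] == 0.0, 1.0, 0.0)

    tops = tree.subtree_maxima()
    births = tree.births()
    persistences = np.array([tops[int(s)] - births[int(s)] for s in sel.selected])

    roots = np.full(n_branches, -1, dtype=np.intp)
    centroids = np.zeros((n_branches, X.shape[1]))
    for b in range(n_branches):
        in_b = np.flatnonzero(labels == b)
        centroids[b] = cluster_centroid(X[graph.members[in_b]], probabilities[in_b])
        d = eccentricity(X[graph.members[in_b]], centroids[b])
        roots[b] = graph.members[in_b[int(np.argmin(d))]]

    return BranchResult(
        labels=labels,
        probabilities=probabilities,
        selected=sel.selected,
        persistences=persistences,
        roots=roots,
        centroids=centroids,
        has_centre=has_centre,
        tree=tree,
        graph=graph,
    )


def detect_branches(
    cluster: ClusterView,
    X: np.ndarray,
    dists: np.ndarray,
    cores: CoreDistanceTable,
    min_branch_size: int = 10,
    approximation_graph: str = "core",
    selection_method: str = "eom",
    selection_persistence: float = 0.0,
    metric: str | callable = "euclidean",
) -> BranchResult:
    """Run the branch-detection stage for one cluster."""
    ecc = eccentricity(X[cluster.members], cluster.centroid, metric)
    if approximation_graph == "full":
        graph = extract_full_graph(cluster, dists, cores, ecc)
    elif approximation_graph == "core":
        graph = extract_core_graph(cluster, dists, cores, ecc)
    else:
        raise ValueError(f"unknown approximation graph variant {approximation_graph!r}")
    return _branches_from_graph(
        graph, ecc, X, min_branch_size, selection_method, selection_persistence
    )


@dataclass
class FLASCResult:
    """Combined cluster + branch output for a whole dataset."""

    labels: np.ndarray
    probabilities: np.ndarray
    cluster_labels: np.ndarray
    cluster_probabilities: np.ndarray
    branch_labels: np.ndarray
    branch_probabilities: np.ndarray
    condensed_tree: CondensedTree = field(repr=False, default=None)
    cluster_views: list[ClusterView] = field(repr=False, default_factory=list)
    branch_results: list[BranchResult] = field(repr=False, default_factory=list)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max() + 1) if (self.labels >= 0).any() else 0


def combine(
    cluster_result: SelectionResult,
    branch_results: list[BranchResult],
    label_sides_as_branches: bool = False,
    prob_combine: str = "average",
) -> FLASCResult:
    """Combine cluster and branch labellings into final labels/probabilities.

    A cluster whose selected branch count is at or below the threshold (2 by
    default, 1 with ``label_sides_as_branches``) contributes a single final
    label — two branches are expected even in unbranched clusters, being the
    two outsides growing towards each other.  Above the threshold each branch
    and, when present, the centre contribute distinct labels.  Probabilities
    combine as the average (default) or product of cluster and branch
    probability.
    """
    if prob_combine not in ("average", "product"):
        raise ValueError(f"unknown prob_combine {prob_combine!r}")
    cluster_labels = cluster_result.labels
    n = len(cluster_labels)
    n_clusters = cluster_result.n_clusters
    if len(branch_results) != n_clusters:
        raise ValueError(
            f"expected {n_clusters} branch results, got {len(branch_results)}"
        )
    threshold = 1 if label_sides_as_branches else 2

    labels = np.full(n, -1, dtype=np.intp)
    branch_labels = np.full(n, -1, dtype=np.intp)
    branch_probabilities = np.zeros(n)
    probabilities = np.zeros(n)

    next_label = 0
    for ci in range(n_clusters):
        br = branch_results[ci]
        members = br.graph.members
        cp = cluster_result.probabilities[members]
        bp = br.probabilities
        if prob_combine == "average":
            combined = 0.5 * (cp + bp)
        else:
            combined = cp * bp
        probabilities[members] = combined
        branch_probabilities[members] = bp
        if br.n_branches <= threshold:
            branch_labels[members] = 0
            labels[members] = next_label
            next_label += 1
        else:
            branch_labels[members] = br.labels
            labels[members] = next_label + br.labels
            next_label += br.n_branches + (1 if br.has_centre else 0)

    return FLASCResult(
        labels=labels,
        probabilities=probabilities,
        cluster_labels=cluster_labels,
        cluster_probabilities=cluster_result.probabilities,
        branch_labels=branch_labels,
        branch_probabilities=branch_probabilities,
        condensed_tree=cluster_result.tree,
        branch_results=branch_results,
    )


def branch_membership_vectors(
    graph: ApproximationGraph,
    branch_result: BranchResult,
    temperature: float = 1.0,
) -> np.ndarray:
    """Soft branch membership from geodesic distances to the branch roots.

    ``d_geo`` is the shortest-path distance in the approximation graph with
    mutual-reachability edge weights; centralities ``c = 1/d_geo`` pass
    through a temperature softmax.  A root's own row is the one-hot vector of
    its branch (the zero-distance limit); every row sums to 1.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    B = branch_result.n_branches
    n = graph.n_vertices
    if B == 0:
        raise ValueError("no branches selected")
    local_root = np.searchsorted(
        np.sort(graph.members), branch_result.roots
    )  # members is sorted ascending
    adj = graph.adjacency()
    d_geo = dijkstra(adj, directed=False, indices=local_root).T  # (n, B)
    if n > 1 and not np.isfinite(d_geo).all():
        raise ValueError("branch root unreachable: approximation graph is disconnected")

    out = np.zeros((n, B))
    zero = d_geo == 0.0
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        c = np.where(d_geo > 0, 1.0 / np.where(d_geo > 0, d_geo, 1.0), np.inf)
    rows = ~any_zero
    if rows.any():
        z = c[rows] / temperature
        z = z - z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        out[rows] = ez / ez.sum(axis=1, keepdims=True)
    if any_zero.any():
        zr = zero[any_zero]
        out[any_zero] = zr / zr.sum(axis=1, keepdims=True)
    return out


def flasc_pipeline(
    X: np.ndarray,
    min_samples: int = 5,
    min_cluster_size: int = 25,
    min_branch_size: int = 10,
    metric: str | callable = "euclidean",
    approximation_graph: str = "core",
    cluster_selection_method: str = "eom",
    branch_selection_method: str = "eom",
    allow_single_cluster: bool = False,
    cluster_selection_epsilon: float = 0.0,
    branch_selection_persistence: float = 0.0,
    label_sides_as_branches: bool = False,
    prob_combine: str = "average",
) -> FLASCResult:
    """Full flare-sensitive clustering: flat density clustering, per-cluster
    branch detection, and label/probability combination."""
    from .hierarchy import _density_stage, _select

    if min_cluster_size < 2:
        raise ValueError(f"min_cluster_size must be >= 2, got {min_cluster_size}")
    if min_branch_size < 2:
        raise ValueError(f"min_branch_size must be >= 2, got {min_branch_size}")
    stage = _density_stage(X, min_samples, min_cluster_size, metric)
    X = stage["X"]
    cluster_result = _select(
        stage["tree"],
        method=cluster_selection_method,
        allow_single=allow_single_cluster,
        selection_epsilon=cluster_selection_epsilon,
        zero_label_single=True,
    )

    views: list[ClusterView] = []
    branch_results: list[BranchResult] = []
    for ci in range(cluster_result.n_clusters):
        members = np.flatnonzero(cluster_result.labels == ci)
        view = build_cluster_view(
            X, members, cluster_result.probabilities[members], stage["mst"]
        )
        views.append(view)
        branch_results.append(
            detect_branches(
                view,
                X,
                stage["dists"],
                stage["cores"],
                min_branch_size=min_branch_size,
                approximation_graph=approximation_graph,
                selection_method=branch_selection_method,
                selection_persistence=branch_selection_persistence,
                metric=metric,
            )
        )

    result = combine(
        cluster_result, branch_results, label_sides_as_branches, prob_combine
    )
    result.cluster_views = views
    return result
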