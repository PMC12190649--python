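"""Branch detection: eccentricity, approximation graphs, branch hierarchies,
label combination and soft membership vectors."""

import numpy as np
import pytest

from flasc import flasc as run_flasc
from flasc.branches import (
    ApproximationGraph,
    _branches_from_graph,
    branch_condensed_tree,
    branch_membership_vectors,
    build_cluster_view,
    cluster_centroid,
    detect_branches,
    eccentricity,
    extract_core_graph,
    extract_full_graph,
)
from flasc.core import build_mst, compute_core_distances, distance_matrix
from flasc.hierarchy import _density_stage, simplify_persistence


# -- centroid and eccentricity ----------------------------------------------


def test_centroid_uniform_is_mean():
    pts = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 3.0]])
    assert np.allclose(cluster_centroid(pts, np.ones(3)), pts.mean(axis=0))


def test_centroid_degenerate_weights():
    pts = np.array([[1.0, 2.0], [5.0, 6.0]])
    assert np.allclose(cluster_centroid(pts, np.array([1.0, 0.0])), pts[0])
    # all-zero probabilities fall back to uniform weights
    assert np.allclose(cluster_centroid(pts, np.zeros(2)), pts.mean(axis=0))


def test_centroid_weighted_example():
    pts = np.array([[0.0, 0.0], [2.0, 0.0]])
    assert np.allclose(cluster_centroid(pts, np.array([1.0, 3.0])), [1.5, 0.0])
    with pytest.raises(ValueError):
        cluster_centroid(np.empty((0, 2)), np.empty(0))


def test_eccentricity_examples():
    pts = np.arange(-2.0, 2.01, 1.0).reshape(-1, 1)
    e = eccentricity(pts, np.zeros(1))
    assert np.allclose(e, [2, 1, 0, 1, 2])
    assert e[2] == 0.0  # the centroid point itself


# -- approximation graphs ----------------------------------------------------


def path_cluster_pieces(path_cloud, k=2):
    X = path_cloud
    stage = _density_stage(X, k, 2)
    members = np.arange(X.shape[0])
    view = build_cluster_view(X, members, np.ones(X.shape[0]), stage["mst"])
    ecc = eccentricity(X, view.centroid)
    return X, stage, view, ecc


def edge_set(g):
    return set(zip(g.u.tolist(), g.v.tolist()))


def test_full_graph_equals_dense_enumeration(path_cloud):
    X, stage, view, ecc = path_cluster_pieces(path_cloud)
    g = extract_full_graph(view, stage["dists"], stage["cores"], ecc)
    M = stage["mreach"]
    expected = {
        (i, j)
        for i in range(5)
        for j in range(i + 1, 5)
        if M[i, j] <= view.d_max
    }
    assert edge_set(g) == expected
    assert edge_set(g) >= set(
        zip(np.minimum(view.mst.u, view.mst.v).tolist(),
            np.maximum(view.mst.u, view.mst.v).tolist())
    )
    assert np.allclose(g.f, np.minimum(ecc[g.u], ecc[g.v]))


def test_core_graph_equals_dense_enumeration(path_cloud):
    X, stage, view, ecc = path_cluster_pieces(path_cloud)
    g = extract_core_graph(view, stage["dists"], stage["cores"], ecc)
    D, kap = stage["dists"], stage["cores"].kappa
    knn = {
        (i, j)
        for i in range(5)
        for j in range(i + 1, 5)
        if D[i, j] <= max(kap[i], kap[j])
    }
    mst_edges = set(
        zip(np.minimum(view.mst.u, view.mst.v).tolist(),
            np.maximum(view.mst.u, view.mst.v).tolist())
    )
    assert edge_set(g) == knn | mst_edges
    assert (0, 1) in edge_set(g) and (3, 4) in edge_set(g)
    assert (0, 4) not in edge_set(g)  # long-range pair absent
    assert g.is_connected()


def test_full_graph_excludes_beyond_dmax(line_fixture):
    X = line_fixture["X"]
    stage = _density_stage(X, 2, 2)
    view = build_cluster_view(X, np.arange(3), np.ones(3), stage["mst"])
    ecc = eccentricity(X, view.centroid)
    g = extract_full_graph(view, stage["dists"], stage["cores"], ecc)
    # pair (0, 2) has mutual reachability 3 > d_max = 2 and is excluded
    assert edge_set(g) == {(0, 1), (1, 2)}


# -- branch condensed trees --------------------------------------------------


def test_branch_tree_constant_eccentricity_single_root():
    n = 6
    u, v = np.arange(n - 1), np.arange(1, n)
    ecc = np.ones(n)
    g = ApproximationGraph("core", np.arange(n), u, v, np.ones(n - 1),
                           np.minimum(ecc[u], ecc[v]))
    tree = branch_condensed_tree(g, ecc, 2)
    assert list(tree.segment_ids()) == [n]


def test_branch_tree_path_two_leaves(path_cloud):
    X, stage, view, ecc = path_cluster_pieces(path_cloud)
    g = extract_core_graph(view, stage["dists"], stage["cores"], ecc)
    tree = branch_condensed_tree(g, ecc, 2)
    leaves = tree.leaves()
    assert len(leaves) == 2
    # the centre point (eccentricity 0) exits the root, after the leaves merge
    assert tree.point_exit_segments()[2] == tree.root
    assert tree.point_exit_values()[2] == 0.0


def test_branch_tree_y_fixture_three_leaves(y_graph_fixture):
    tree = branch_condensed_tree(
        y_graph_fixture["graph"], y_graph_fixture["ecc"], 2
    )
    assert len(tree.leaves()) == 3
    # centre point exits at the merge value, from the root segment
    assert tree.point_exit_segments()[0] == tree.root


def test_branch_tree_rejects_disconnected():
    ecc = np.array([1.0, 1.0, 2.0, 2.0])
    g = ApproximationGraph("core", np.arange(4), np.array([0, 2]), np.array([1, 3]),
                           np.ones(2), np.ones(2))
    with pytest.raises(ValueError, match="disconnected"):
        branch_condensed_tree(g, ecc, 2)


def test_simplify_persistence_identity_and_collapse(path_cloud):
    X, stage, view, ecc = path_cluster_pieces(path_cloud)
    g = extract_core_graph(view, stage["dists"], stage["cores"], ecc)
    tree = branch_condensed_tree(g, ecc, 2)
    assert simplify_persistence(tree, 0.0) is tree
    # leaf persistences are 1 each: threshold 1.5 collapses to the root
    collapsed = simplify_persistence(tree, 1.5)
    assert list(collapsed.segment_ids()) == [collapsed.root]
    # threshold above the global range always collapses
    huge = simplify_persistence(tree, 100.0)
    assert list(huge.segment_ids()) == [huge.root]


# -- detect_branches ---------------------------------------------------------


def test_detect_branches_y_fixture(y_graph_fixture):
    br = _branches_from_graph(
        y_graph_fixture["graph"], y_graph_fixture["ecc"], y_graph_fixture["X"],
        min_branch_size=2, selection_method="leaf",
    )
    assert br.n_branches == 3
    assert br.has_centre and br.labels[0] == 3  # origin gets the centre label
    assert len(np.unique(br.labels)) == 4
    assert np.all(br.persistences >= 0)
    # branch roots are members of their own branches
    for b in range(3):
        assert br.labels[np.flatnonzero(br.graph.members == br.roots[b])[0]] == b


def test_detect_branches_convex_blob_at_most_two():
    X = np.random.default_rng(7).normal(0, 1.0, (100, 2))
    for method in ("leaf", "eom"):
        res = run_flasc(
            X, min_samples=5, min_cluster_size=25, min_branch_size=10,
            allow_single_cluster=True, branch_selection_method=method,
        )
        assert res.branch_results[0].n_branches <= 2


def test_detect_branches_path_exactly_two(path_cloud):
    res = run_flasc(
        path_cloud, min_samples=2, min_cluster_size=2, min_branch_size=2,
        allow_single_cluster=True, branch_selection_method="leaf",
    )
    assert res.branch_results[0].n_branches == 2


def test_detect_branches_via_cluster_view(path_cloud):
    stage = _density_stage(path_cloud, 2, 2)
    view = build_cluster_view(path_cloud, np.arange(5), np.ones(5), stage["mst"])
    br = detect_branches(
        view, path_cloud, stage["dists"], stage["cores"],
        min_branch_size=2, approximation_graph="core", selection_method="leaf",
    )
    assert br.n_branches == 2 and br.has_centre


# -- combination -------------------------------------------------------------


def test_combine_two_branch_clusters_merge_to_single_labels():
    xs = np.arange(40) * 0.1
    X = np.vstack([np.c_[xs, np.zeros(40)], np.c_[xs, np.full(40, 10.0)]])
    res = run_flasc(X, min_samples=3, min_cluster_size=10, min_branch_size=5)
    assert res.labels.max() + 1 == 2
    assert all(br.n_branches == 2 for br in res.branch_results)
    # merged clusters report the single merged branch label
    assert np.all(res.branch_labels[res.labels >= 0] == 0)

    sides = run_flasc(
        X, min_samples=3, min_cluster_size=10, min_branch_size=5,
        label_sides_as_branches=True,
    )
    assert sides.labels.max() + 1 == 6  # 2 sides + centre, per cluster


def test_combine_three_branches_and_centre_four_labels():
    rng = np.random.default_rng(1)
    arms = []
    for a in np.deg2rad([90, 210, 330]):
        t = np.linspace(0.05, 2.0, 30)
        arms.append(np.c_[t * np.cos(a), t * np.sin(a)] + rng.normal(0, 0.02, (30, 2)))
    Y = np.vstack(arms)
    res = run_flasc(
        Y, min_samples=5, min_cluster_size=20, min_branch_size=8,
        allow_single_cluster=True, branch_selection_method="leaf",
    )
    assert res.cluster_labels.max() + 1 == 1
    assert res.branch_results[0].n_branches == 3
    assert res.labels.max() + 1 == 4
    assert np.all(res.labels >= 0)  # no noise among cluster members


def test_probability_combination_rules():
    xs = np.arange(40) * 0.1
    X = np.vstack([np.c_[xs, np.zeros(40)], np.c_[xs, np.full(40, 10.0)]])
    avg = run_flasc(X, min_samples=3, min_cluster_size=10, min_branch_size=5)
    prod = run_flasc(
        X, min_samples=3, min_cluster_size=10, min_branch_size=5,
        prob_combine="product",
    )
    cp, bp = avg.cluster_probabilities, avg.branch_probabilities
    assert np.allclose(avg.probabilities, 0.5 * (cp + bp))
    assert np.allclose(prod.probabilities, cp * bp)
    assert np.all((avg.probabilities >= 0) & (avg.probabilities <= 1))


def test_combine_mismatched_inputs_raise():
    from flasc.branches import combine
    from flasc.hierarchy import SelectionResult

    sel = SelectionResult(
        labels=np.array([0, 0, 1, 1]),
        probabilities=np.ones(4),
        selected=np.array([5, 6]),
        stabilities={},
    )
    with pytest.raises(ValueError):
        combine(sel, [])


# -- membership vectors ------------------------------------------------------


def _seven_path_graph(weights):
    """A 7-vertex path with eccentricities (3,2,1,0,1,2,3): two 3-point arms
    around a central junction; roots land on the middle arm points."""
    ecc = np.array([3.0, 2.0, 1.0, 0.0, 1.0, 2.0, 3.0])
    u = np.arange(6)
    v = np.arange(1, 7)
    g = ApproximationGraph("core", np.arange(7), u, v,
                           np.asarray(weights, dtype=float),
                           np.minimum(ecc[u], ecc[v]))
    X = np.arange(-3.0, 3.01, 1.0).reshape(-1, 1)
    br = _branches_from_graph(g, ecc, X, min_branch_size=2, selection_method="leaf")
    return g, br


def test_membership_symmetric_point_is_half_half():
    g, br = _seven_path_graph(np.ones(6))
    assert br.n_branches == 2
    assert set(br.roots.tolist()) == {1, 5}  # the middle points of each arm
    m = branch_membership_vectors(g, br)
    assert np.allclose(m.sum(axis=1), 1.0)
    assert np.allclose(m[3], [0.5, 0.5])  # geodesically equidistant junction
    for b, root in enumerate(br.roots):
        local = int(np.flatnonzero(g.members == root)[0])
        assert np.allclose(m[local], np.eye(2)[b])


def test_membership_softmax_values():
    # junction: d_geo = 2 to the left root, 1 to the right root;
    # at t=1 the softmax of c = (1/2, 1) is (0.3775, 0.6225)
    g, br = _seven_path_graph([1.0, 1.0, 1.0, 0.5, 0.5, 1.0])
    assert set(br.roots.tolist()) == {1, 5}
    m = branch_membership_vectors(g, br)
    z = np.exp([0.5, 1.0])
    expected = z / z.sum()
    assert np.allclose(np.sort(m[3]), np.sort(expected))
    assert np.allclose(np.sort(m[3]), [0.37754067, 0.62245933], atol=1e-6)


def test_membership_requires_positive_temperature(y_graph_fixture):
    br = _branches_from_graph(
        y_graph_fixture["graph"], y_graph_fixture["ecc"], y_graph_fixture["X"],
        min_branch_size=2, selection_method="leaf",
    )
    with pytest.raises(ValueError):
        branch_membership_vectors(y_graph_fixture["graph"], br, temperature=0.0)


# -- invariants on realistic data -------------------------------------------


def test_lipschitz_bound_on_graph_edges(star_fit):
    """|e(u) - e(v)| <= d_mreach(u, v) for every approximation-graph edge."""
    est = star_fit["est"]
    X = star_fit["X"]
    for view, g in zip(est.result_.cluster_views, est.approximation_graphs_):
        ecc = eccentricity(X[g.members], view.centroid)
        assert np.all(np.abs(ecc[g.u] - ecc[g.v]) <= g.w + 1e-9)
        # the cluster MST is a subgraph
        mst_edges = set(zip(np.minimum(view.mst.u, view.mst.v).tolist(),
                            np.maximum(view.mst.u, view.mst.v).tolist()))
        assert mst_edges <= set(zip(g.u.tolist(), g.v.tolist()))


def test_branch_labels_partition_members(star_fit):
    est = star_fit["est"]
    for br in est.result_.branch_results:
        labs = br.labels
        assert labs.min() >= 0
        top = br.n_branches if br.has_centre else br.n_branches - 1
        assert labs.max() == top


def test_min_branch_size_monotonicity():
    """Raising the minimum branch size never increases the branch count."""
    from flasc.synthetic import StarSpec, generate_star_dataset

    spec = StarSpec(
        branch_counts=(5,), branch_lengths=(2.0,), noise_levels=(0.02,),
        points_per_branch=(20,), noise_fraction=0.0, seed=0,
    )
    X, _ = generate_star_dataset(spec)
    counts = []
    for m_b in range(2, 21):
        res = run_flasc(
            X, min_samples=3, min_cluster_size=20, min_branch_size=m_b,
            allow_single_cluster=True, cluster_selection_method="eom",
            branch_selection_method="leaf",
        )
        counts.append(res.branch_results[0].n_branches)
    assert counts[0] >= counts[-1]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_estimator_deterministic(star_fit):
    from flasc import FLASC

    X = star_fit["X"]
    params = dict(
        min_samples=6, min_cluster_size=70, min_branch_size=10,
        approximation_graph="core", cluster_selection_method="leaf",
        branch_selection_method="leaf",
    )
    a = FLASC(**params).fit(X)
    assert np.array_equal(a.labels_, star_fit["est"].labels_)
    assert np.array_equal(a.probabilities_, star_fit["est"].probabilities_)
    assert np.array_equal(a.branch_labels_, star_fit["est"].branch_labels_)


def test_estimator_sklearn_contract():
    from sklearn.base import clone

    from flasc import FLASC

    est = FLASC(min_cluster_size=5)
    params = est.get_params()
    assert params["min_cluster_size"] == 5
    clone(est)  # must be cloneable
    X = np.random.default_rng(0).normal(size=(30, 2))
    labels = FLASC(min_samples=3, min_cluster_size=5, min_branch_size=2).fit_predict(X)
    assert labels.shape == (30,)
    with pytest.raises(ValueError):
        FLASC(min_samples=100).fit(X)
    with pytest.raises(Exception):
        FLASC(min_cluster_size=1).fit(X)


def test_all_noise_when_no_cluster_possible():
    # N < min_cluster_size without allow_single: an all-noise result, not an error
    X = np.random.default_rng(0).normal(size=(10, 2))
    res = run_flasc(X, min_samples=2, min_cluster_size=50)
    assert np.all(res.labels == -1)
    assert np.all(res.probabilities == 0)
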