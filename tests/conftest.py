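import numpy as np
import pytest

from flasc.core import compute_core_distances, distance_matrix


@pytest.fixture(scope="session")
def line_fixture():
    """1-D points (0), (1), (3) with self-inclusive k=2 core distances."""
    X = np.array([[0.0], [1.0], [3.0]])
    dists = distance_matrix(X)
    cores = compute_core_distances(X, 2, dists=dists)
    return {"X": X, "dists": dists, "cores": cores}


@pytest.fixture(scope="session")
def y_graph_fixture():
    """Hand-built Y: a centre point plus three 2-point arms at radii 1 and 2
    along 120-degree separated directions, with path edges per arm."""
    from flasc.branches import ApproximationGraph

    angles = np.deg2rad([0.0, 120.0, 240.0])
    pts = [np.zeros(2)]
    for a in angles:
        d = np.array([np.cos(a), np.sin(a)])
        pts.extend([d, 2.0 * d])
    X = np.array(pts)
    ecc = np.linalg.norm(X, axis=1)
    u = np.array([0, 1, 0, 3, 0, 5])
    v = np.array([1, 2, 3, 4, 5, 6])
    graph = ApproximationGraph(
        variant="core",
        members=np.arange(7),
        u=u,
        v=v,
        w=np.ones(6),
        f=np.minimum(ecc[u], ecc[v]),
    )
    return {"X": X, "ecc": ecc, "graph": graph}


@pytest.fixture(scope="session")
def path_cloud():
    """A straight 1-D path cluster at -2, -1, 0, 1, 2."""
    return np.arange(-2.0, 2.01, 1.0).reshape(-1, 1)


@pytest.fixture(scope="session")
def star_fit():
    """A default 2-D star dataset fitted with the benchmark parameters."""
    from flasc import FLASC
    from flasc.synthetic import StarSpec, generate_star_dataset

    X, y = generate_star_dataset(StarSpec(seed=0))
    est = FLASC(
        min_samples=6,
        min_cluster_size=70,
        min_branch_size=10,
        approximation_graph="core",
        cluster_selection_method="leaf",
        branch_selection_method="leaf",
    ).fit(X)
    return {"X": X, "y": y, "est": est}
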