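"""Scikit-learn style estimator for flare-sensitive clustering."""

from __future__ import annotations

from numbers import Integral, Real

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils._param_validation import Interval, StrOptions
from sklearn.utils.validation import check_is_fitted, validate_data

from .branches import FLASCResult, branch_membership_vectors, flasc_pipeline


class FLASC(ClusterMixin, BaseEstimator):
    """Flare-sensitive clustering.

    Density-based clustering (an HDBSCAN*-style backbone: core distances,
    mutual reachability, exact MST, condensed hierarchy, excess-of-mass or
    leaf selection) followed by a per-cluster branch-detection stage that
    builds an eccentricity-based branching hierarchy on a cluster
    approximation graph and emits combined cluster+branch labels.

    Parameters
    ----------
    min_samples : int, default=5
        Neighbour count ``k`` for the core distance (self-inclusive); the
        density smoothing factor.
    min_cluster_size : int, default=25
        Minimum number of points for a split side to count as a cluster.
    min_branch_size : int, default=10
        Minimum number of points for a split side to count as a branch.
    metric : str or callable, default="euclidean"
        Distance metric between feature vectors.
    approximation_graph : {"core", "full"}, default="core"
        Connectivity used inside clusters: the cluster-restricted k-NN graph
        union the cluster MST ("core"), or all member pairs within the
        longest cluster-MST mutual reachability ("full").
    cluster_selection_method, branch_selection_method : {"eom", "leaf"}
        Segment selection strategy for the density and eccentricity
        hierarchies respectively.
    allow_single_cluster : bool, default=False
        Let the density stage select the hierarchy root.  When it does (and
        ``cluster_selection_epsilon`` is unused) all points receive cluster
        label 0 so single-cluster data stays analysable for branches.
    cluster_selection_epsilon : float, default=0.0
        Minimum birth distance for selected clusters (distance units).
    branch_selection_persistence : float, default=0.0
        Minimum eccentricity range a branch must persist for.
    label_sides_as_branches : bool, default=False
        Give separate final labels already at 2 branches (threshold 1
        instead of 2), separating the two ends of elongated clusters.
    prob_combine : {"average", "product"}, default="average"
        How cluster and branch probabilities merge into the final one.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Final combined labels; -1 is noise.
    probabilities_ : ndarray of shape (n_samples,)
        Combined membership strengths in [0, 1]; 0 for noise.
    cluster_labels_, cluster_probabilities_ : ndarray
        Density-stage labels/probabilities.
    branch_labels_, branch_probabilities_ : ndarray
        Within-cluster sub-labels (0..B-1, centre label B; a single merged 0
        for clusters at or below the branch-count threshold).
    condensed_tree_ : CondensedTree
        Density condensed hierarchy.
    branch_condensed_trees_ : list of CondensedTree
        Per-cluster eccentricity hierarchies (superlevel orientation).
    approximation_graphs_ : list of ApproximationGraph
    branch_persistences_ : list of ndarray
        Eccentricity ranges of each cluster's selected branches.

    Examples
    --------
    >>> import numpy as np
    >>> from flasc import FLASC
    >>> theta = np.linspace(0, 2 * np.pi, 120, endpoint=False)
    >>> X = np.c_[np.cos(theta), np.sin(theta)]  # a ring: no flares
    >>> int(FLASC(min_cluster_size=20, allow_single_cluster=True).fit(X).labels_.max())
    0
    """

    _parameter_constraints: dict = {
        "min_samples": [Interval(Integral, 1, None, closed="left")],
        "min_cluster_size": [Interval(Integral, 2, None, closed="left")],
        "min_branch_size": [Interval(Integral, 2, None, closed="left")],
        "metric": [str, callable],
        "approximation_graph": [StrOptions({"core", "full"})],
        "cluster_selection_method": [StrOptions({"eom", "leaf"})],
        "branch_selection_method": [StrOptions({"eom", "leaf"})],
        "allow_single_cluster": ["boolean"],
        "cluster_selection_epsilon": [Interval(Real, 0, None, closed="left")],
        "branch_selection_persistence": [Interval(Real, 0, None, closed="left")],
        "label_sides_as_branches": ["boolean"],
        "prob_combine": [StrOptions({"average", "product"})],
    }

    def __init__(
        self,
        min_samples: int = 5,
        min_cluster_size: int = 25,
        min_branch_size: int = 10,
        metric="euclidean",
        approximation_graph: str = "core",
        cluster_selection_method: str = "eom",
        branch_selection_method: str = "eom",
        allow_single_cluster: bool = False,
        cluster_selection_epsilon: float = 0.0,
        branch_selection_persistence: float = 0.0,
        label_sides_as_branches: bool = False,
        prob_combine: str = "average",
    ):
        self.min_samples = min_samples
        self.min_cluster_size = min_cluster_size
        self.min_branch_size = min_branch_size
        self.metric = metric
        self.approximation_graph = approximation_graph
        self.cluster_selection_method = cluster_selection_method
        self.branch_selection_method = branch_selection_method
        self.allow_single_cluster = allow_single_cluster
        self.cluster_selection_epsilon = cluster_selection_epsilon
        self.branch_selection_persistence = branch_selection_persistence
        self.label_sides_as_branches = label_sides_as_branches
        self.prob_combine = prob_combine

    def fit(self, X, y=None) -> "FLASC":
        """Run flare-sensitive clustering on ``X`` (shape (n_samples, n_features))."""
        self._validate_params()
        X = validate_data(self, X, ensure_min_samples=1, dtype=np.float64)
        if self.min_samples > X.shape[0]:
            raise ValueError(
                f"min_samples={self.min_samples} is larger than n_samples={X.shape[0]}"
            )
        result = flasc_pipeline(
            X,
            min_samples=self.min_samples,
            min_cluster_size=self.min_cluster_size,
            min_branch_size=self.min_branch_size,
            metric=self.metric,
            approximation_graph=self.approximation_graph,
            cluster_selection_method=self.cluster_selection_method,
            branch_selection_method=self.branch_selection_method,
            allow_single_cluster=self.allow_single_cluster,
            cluster_selection_epsilon=self.cluster_selection_epsilon,
            branch_selection_persistence=self.branch_selection_persistence,
            label_sides_as_branches=self.label_sides_as_branches,
            prob_combine=self.prob_combine,
        )
        self.result_ = result
        self.labels_ = result.labels
        self.probabilities_ = result.probabilities
        self.cluster_labels_ = result.cluster_labels
        self.cluster_probabilities_ = result.cluster_probabilities
        self.branch_labels_ = result.branch_labels
        self.branch_probabilities_ = result.branch_probabilities
        self.condensed_tree_ = result.condensed_tree
        self.branch_condensed_trees_ = [br.tree for br in result.branch_results]
        self.approximation_graphs_ = [br.graph for br in result.branch_results]
        self.branch_persistences_ = [br.persistences for br in result.branch_results]
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def branch_membership(self, cluster_index: int, temperature: float = 1.0) -> np.ndarray:
        """Soft branch-membership matrix for one fitted cluster.

        Rows (one per cluster member, in ``approximation_graphs_[i].members``
        order) lie on the probability simplex; branch-root rows are one-hot.
        """
        check_is_fitted(self, "result_")
        br = self.result_.branch_results[cluster_index]
        return branch_membership_vectors(br.graph, br, temperature)


def flasc(X, **params) -> FLASCResult:
    """Functional interface: fit :class:`FLASC` and return the full result."""
    est = FLASC(**params)
    est.fit(X)
    return est.result_
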