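"""Adjusted Rand Index scoring and the fixed-parameter star benchmark."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .estimator import flasc
from .hierarchy import flat_clusters
from .synthetic import StarSpec, generate_star_dataset

# Benchmark parameter settings per dimensionality (the grid-search optima of
# the star benchmark): FLASC runs with a core/full approximation graph and a
# selection strategy used for both clusters and branches; the cluster-only
# baseline runs the density backbone alone.
FLASC_STAR_PARAMS: dict[int, dict] = {
    2: dict(approximation_graph="core", cluster_selection_method="leaf",
            branch_selection_method="leaf", min_samples=6, min_cluster_size=70,
            min_branch_size=10),
    8: dict(approximation_graph="core", cluster_selection_method="leaf",
            branch_selection_method="leaf", min_samples=6, min_cluster_size=100,
            min_branch_size=8),
    16: dict(approximation_graph="core", cluster_selection_method="leaf",
             branch_selection_method="leaf", min_samples=2, min_cluster_size=84,
             min_branch_size=14),
}
BASELINE_STAR_PARAMS: dict[int, dict] = {
    2: dict(cluster_selection_method="eom", min_samples=2, min_cluster_size=20),
    8: dict(cluster_selection_method="eom", min_samples=20, min_cluster_size=20),
    16: dict(cluster_selection_method="leaf", min_samples=2, min_cluster_size=58),
}


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert–Arabie chance-corrected partition agreement in [-1, 1].

    Noise labels (-1) are treated as an ordinary class: the comparison is
    between full partitions of the data, outliers included.
    """
    labels_a = np.asarray(labels_a).ravel()
    labels_b = np.asarray(labels_b).ravel()
    if labels_a.shape != labels_b.shape:
        raise ValueError(
            f"label vectors differ in length: {labels_a.shape[0]} vs {labels_b.shape[0]}"
        )
    if labels_a.shape[0] < 2:
        raise ValueError("need at least two observations")
    return float(adjusted_rand_score(labels_a, labels_b))


@dataclass
class BenchmarkReport:
    """Per-seed and mean ARI of FLASC and the cluster-only baseline."""

    dims: int
    seeds: list[int]
    flasc_ari: list[float]
    baseline_ari: list[float]
    flasc_params: dict = field(default_factory=dict)
    baseline_params: dict = field(default_factory=dict)

    @property
    def flasc_mean(self) -> float:
        return float(np.mean(self.flasc_ari))

    @property
    def baseline_mean(self) -> float:
        return float(np.mean(self.baseline_ari))

    def to_dict(self) -> dict:
        return {
            "dims": self.dims,
            "seeds": list(self.seeds),
            "flasc_ari": list(self.flasc_ari),
            "baseline_ari": list(self.baseline_ari),
            "flasc_mean": self.flasc_mean,
            "baseline_mean": self.baseline_mean,
            "flasc_params": dict(self.flasc_params),
            "baseline_params": dict(self.baseline_params),
        }


def run_star_benchmark(
    n_seeds: int = 5,
    dims: int = 2,
    seeds: list[int] | None = None,
) -> BenchmarkReport:
    """Generate star datasets and score FLASC against the cluster-only baseline.

    For each seed a default star dataset is sampled at ``dims`` dimensions;
    FLASC and the density-only baseline run with the fixed benchmark
    parameters for that dimensionality, and both labelings are scored with
    ARI against the branch-level ground truth (noise as a class).
    """
    if dims not in FLASC_STAR_PARAMS:
        raise ValueError(f"no benchmark parameters for dims={dims}")
    if seeds is None:
        seeds = list(range(n_seeds))
    fp = FLASC_STAR_PARAMS[dims]
    bp = BASELINE_STAR_PARAMS[dims]
    flasc_ari, baseline_ari = [], []
    for seed in seeds:
        X, y = generate_star_dataset(StarSpec(n_dims=dims, seed=int(seed)))
        res = flasc(X, **fp)
        flasc_ari.append(adjusted_rand_index(y, res.labels))
        base = flat_clusters(X, **bp)
        baseline_ari.append(adjusted_rand_index(y, base.labels))
    return BenchmarkReport(
        dims=dims,
        seeds=[int(s) for s in seeds],
        flasc_ari=flasc_ari,
        baseline_ari=baseline_ari,
        flasc_params=dict(fp),
        baseline_params=dict(bp),
    )
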