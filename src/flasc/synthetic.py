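"""Synthetic benchmark generators: star-shaped clusters and Gaussian random walks.

The star family stresses branch detection: branches carry no separating
low-density gap, points are exponentially spaced from the centre outwards so
density is highest at each star's centre and lowest at the branch ends, and
a uniform background simulates outliers.  The random-walk family produces
point clouds with non-trivially varying density and branching structure in
every dimension, for scaling studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class StarSpec:
    """Parameters of the four-star benchmark dataset.

    Per star: number of branches, branch length, noise level ``n_r`` and
    points per branch.  The noise level converts to a per-dimension jitter
    standard deviation ``sigma = n_r * sqrt(1/n_dims)``.  Structure lives in
    the first two dimensions; any extra dimensions contain jitter only.
    ``noise_fraction`` of the clean point count is added as uniform
    background over the clean bounding box expanded by ``box_pad`` of its
    range per side, emulating widely scattered outliers.  ``growth`` is the
    total growth factor of the exponential radial spacing along a branch.
    """

    branch_counts: tuple[int, ...] = (3, 4, 5, 10)
    branch_lengths: tuple[float, ...] = (1.8, 2.3, 2.0, 3.5)
    noise_levels: tuple[float, ...] = (0.2, 0.2, 0.02, 0.1)
    points_per_branch: tuple[int, ...] = (40, 150, 20, 100)
    n_dims: int = 2
    noise_fraction: float = 0.05
    growth: float = 2.0
    box_pad: float = 1.5
    seed: int = 0

    def __post_init__(self):
        lens = {
            len(self.branch_counts),
            len(self.branch_lengths),
            len(self.noise_levels),
            len(self.points_per_branch),
        }
        if len(lens) != 1:
            raise ValueError("per-star parameter tuples must have equal length")
        if any(b < 1 for b in self.branch_counts):
            raise ValueError("branch counts must be >= 1")
        if any(l <= 0 for l in self.branch_lengths):
            raise ValueError("branch lengths must be positive")
        if any(p < 1 for p in self.points_per_branch):
            raise ValueError("points per branch must be >= 1")
        if not (0 <= self.noise_fraction < 1):
            raise ValueError("noise fraction must lie in [0, 1)")
        if self.n_dims < 2:
            raise ValueError("stars need at least 2 dimensions")
        if self.growth <= 1:
            raise ValueError("growth must exceed 1 (density must decrease outwards)")
        if self.box_pad < 0:
            raise ValueError("box_pad must be non-negative")

    @property
    def n_stars(self) -> int:
        return len(self.branch_counts)

    @property
    def n_branches_total(self) -> int:
        return sum(self.branch_counts)

    @property
    def clean_count(self) -> int:
        return sum(b * p for b, p in zip(self.branch_counts, self.points_per_branch))

    @property
    def n_background(self) -> int:
        return int(round(self.noise_fraction * self.clean_count))


def _branch_radii(n: int, length: float, growth: float = 2.0) -> np.ndarray:
    """Radii of ``n`` points exponentially spaced over ``(0, length]``.

    Length-normalised exponential spacing: the i-th radius is
    ``length * (G^(i/n) - 1) / (G - 1)`` with total growth factor ``G``, so
    the radial density profile is independent of the per-branch point count
    and decreases monotonically from the centre to the branch end (local
    spacing grows by a factor ``G`` along the branch).
    """
    t = np.arange(1, n + 1, dtype=np.float64) / n
    return length * (growth**t - 1.0) / (growth - 1.0)


def _star_centres(n_stars: int, max_length: float) -> np.ndarray:
    """Deterministic star positions: corners of a grid with spacing three
    times the maximum branch length, so inter-star gaps dominate."""
    side = int(np.ceil(np.sqrt(n_stars)))
    spacing = 3.0 * max_length
    centres = [(spacing * (i % side), spacing * (i // side)) for i in range(n_stars)]
    return np.asarray(centres[:n_stars], dtype=np.float64)


def generate_star_dataset(spec: StarSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample the star benchmark.

    Returns
    -------
    X : ndarray of shape (n_points, n_dims)
    y : ndarray of int
        Ground truth: one label per branch (0..n_branches_total-1, star-major)
        and -1 for the uniform background.
    """
    ss = np.random.SeedSequence(spec.seed)
    star_streams = [np.random.default_rng(s) for s in ss.spawn(spec.n_stars + 1)]
    noise_rng = star_streams.pop()

    D = spec.n_dims
    centres = _star_centres(spec.n_stars, max(spec.branch_lengths))
    points: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    label = 0
    for s in range(spec.n_stars):
        rng = star_streams[s]
        n_branches = spec.branch_counts[s]
        length = spec.branch_lengths[s]
        ppb = spec.points_per_branch[s]
        sigma = spec.noise_levels[s] * np.sqrt(1.0 / D)
        angles = 2.0 * np.pi * np.arange(n_branches) / n_branches
        for b in range(n_branches):
            radii = _branch_radii(ppb, length, spec.growth)
            base = np.zeros((ppb, D))
            base[:, 0] = centres[s, 0] + radii * np.cos(angles[b])
            base[:, 1] = centres[s, 1] + radii * np.sin(angles[b])
            base += rng.normal(0.0, sigma, size=(ppb, D))
            points.append(base)
            labels.append(np.full(ppb, label, dtype=np.intp))
            label += 1

    clean = np.vstack(points)
    n_bg = spec.n_background
    if n_bg > 0:
        lo, hi = clean.min(axis=0), clean.max(axis=0)
        pad = spec.box_pad * (hi - lo)
        bg = noise_rng.uniform(lo - pad, hi + pad, size=(n_bg, D))
        X = np.vstack([clean, bg])
        y = np.concatenate(labels + [np.full(n_bg, -1, dtype=np.intp)])
    else:
        X, y = clean, np.concatenate(labels)
    return X, y


@dataclass(frozen=True)
class WalkSpec:
    """Parameters of the Gaussian random-walk dataset: ``n_starts`` uniform
    starting points in a hypercube sized to fit five times the number of
    to-be-generated clusters, each spawning ``walks_per_start`` walks of
    ``n_steps`` steps; every step perturbs one uniformly chosen dimension by
    ``N(0, step_scale)``."""

    n_starts: int = 2
    n_dims: int = 2
    walks_per_start: int = 5
    n_steps: int = 50
    step_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_starts, self.n_dims, self.walks_per_start, self.n_steps) < 1:
            raise ValueError("all counts must be positive")
        if self.step_scale <= 0:
            raise ValueError("step scale must be positive")

    @property
    def n_points(self) -> int:
        return self.n_starts * self.walks_per_start * self.n_steps


def generate_random_walk_dataset(spec: WalkSpec) -> np.ndarray:
    """Sample the random-walk dataset; rows are all step positions."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    side = 2.0 * (5.0 * spec.n_starts) ** (1.0 / spec.n_dims)
    starts = rng.uniform(0.0, side, size=(spec.n_starts, spec.n_dims))
    out = np.empty((spec.n_points, spec.n_dims))
    row = 0
    for s in range(spec.n_starts):
        for _ in range(spec.walks_per_start):
            pos = starts[s].copy()
            for _ in range(spec.n_steps):
                dim = int(rng.integers(spec.n_dims))
                pos[dim] += rng.normal(0.0, spec.step_scale)
                out[row] = pos
                row += 1
    return out
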