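# Methods

This note records the model, the numerical conventions, and the design
choices behind `flasc`, at the level of detail a maintainer needs to reason
about edge cases.

## Model and assumptions

Flare-sensitive clustering composes two filtrations.

**Density filtration.** The density at a point is estimated as the
reciprocal of its core distance, the distance to its k-th nearest neighbour
under a *self-inclusive* ordering (the point is its own first neighbour, so
k=1 degenerates to raw distances and duplicate points get core distance 0).
Mutual reachability max(κ_i, κ_j, d_ij) supplies connectivity: tracking
connected components of density superlevel sets while the threshold
decreases is equivalent to single linkage over the mutual-reachability
minimum spanning tree.  The hierarchy is condensed under a minimum cluster
size m_c: a merge only counts as a true split when both sides hold at least
m_c points; smaller sides "fall out" of the surviving segment at the merge
value.  Excess-of-mass selection maximises total segment stability (the sum
of per-point density ranges) over antichains of the condensed tree; leaf
selection takes all leaves.

**Eccentricity filtration.** Within each selected cluster, eccentricity is
the distance to the cluster's membership-probability-weighted centroid.
Branches are connected components of eccentricity superlevel sets.
Connectivity comes from a cluster approximation graph: *core* = the
cluster-restricted k-NN graph united with the cluster MST (cheap, robust
when clusters span wide density ranges); *full* = all member pairs whose
mutual reachability is at most the longest cluster-MST edge (denser, better
for branches at the lowest in-cluster density).  Edges carry the filtration
value f = min(e_u, e_v), the eccentricity of the least eccentric endpoint;
processing edges in decreasing f and condensing under a minimum branch size
m_b yields the branching hierarchy.  Branch persistence is the eccentricity
range between a branch's tip and its merge; `branch_selection_persistence`
iteratively dissolves leaves below a persistence floor.

Assumptions worth stating: the eccentricity field is only a proxy for the
cluster's intrinsic shape — a U-shaped cluster has the same eccentricity
profile as a Y-shaped one because the centroid sits between the arms; and
the approximation graphs assume the density stage removed surrounding
noise, since absorbed outliers between two arms act as bridges that can
merge branches high in the filtration.

## One condensation engine; multi-way tie events

Both filtrations are join trees processed from high to low value (density
uses λ = 1/distance, branches use f directly), so one union-find condenser
serves both.  Equal-valued merge events are processed as a single
*multi-way* event rather than in an arbitrary binary order.  This matters
exactly at cluster centres: the centre point's own entry value coincides
with the value at which the surrounding branches connect, and a binary
tie-break would absorb the centre into whichever branch is processed first.
With batched events the centre falls out of the *parent* segment and
correctly receives the centre label.  On continuous data (no exact ties)
the batched engine reduces to the classical binary algorithm; the test
suite verifies exact agreement — labels and probabilities — with
scikit-learn's HDBSCAN implementation across parameter settings.

Conventions inside the engine:

- Segment ids are assigned breadth-first from the root; the root id equals
  the point count (points occupy 0..N-1).
- The root's birth value is 0 — the minimum density (or eccentricity) at
  which the component exists — matching the reference implementation
  family.  This makes the root's stability large, so excess-of-mass with
  `allow_single_cluster` usually selects the root on unimodal data.
- Zero-distance merges map to λ = +∞ and are processed first: duplicate
  points are inseparable.
- Distance and filtration ties break lexicographically by vertex index
  everywhere (MST construction, edge ordering), so repeated runs are
  bit-identical.
- Membership probability is the point's exit value over the largest exit
  value among the selected segment's direct entries, clamped to [0, 1];
  noise points get 0.
- `cluster_selection_epsilon` is a *distance* threshold: selected clusters
  born closer than epsilon are replaced by their first ancestor born at a
  distance of at least epsilon (the root only when a single cluster is
  allowed).  It applies to both EOM and leaf selection.  The branch-stage
  analogue is a *persistence range*, not a single threshold, because
  branches need not start at zero eccentricity.

## Branch labelling details

Branch-stage selection always allows the hierarchy root (a cluster with no
sub-branches is one branch).  Points left unlabelled by branch selection —
those entering the filtration after the selected branches have connected —
receive the centre label, numbered after the branches.  The centre
probability is clamp(1 − e(x)/e_merge, 0, 1), where e_merge is the smallest
birth value among selected branches (the eccentricity at which the last two
join); if e_merge is 0 the degenerate value 1 is used for points exactly at
the centroid and 0 otherwise.  The probability formula for branches reuses
the exit/max-exit rule on the eccentricity scale.

Final labels: a cluster contributes one label when its branch count is at
or below the threshold (2 by default — any cluster's two outsides grow
towards each other; 1 with `label_sides_as_branches`), else one label per
branch plus the centre.  In the merged case the per-point branch labels are
reported as a single 0 while branch probabilities keep their computed
values; final probability is the average (default) or product of cluster
and branch probability.

Soft branch-membership vectors use geodesic distances in the approximation
graph with mutual-reachability edge weights, from each branch's root (the
member nearest the branch's weighted centroid; ties pick the lowest index).
Centralities 1/d_geo pass through a softmax with temperature t (default
1.0, chosen as the natural scale-free default); zero geodesic distance is
handled as the one-hot limit rather than by ∞ arithmetic.

## Synthetic data

The star generator emulates branch structures with no separating density
gap: four stars with 3/4/5/10 branches, lengths 1.8/2.3/2.0/3.5, noise
levels 0.2/0.2/0.02/0.1 and 40/150/20/100 points per branch; evenly spread
branch angles; Gaussian jitter with σ = n_r·√(1/D) in all D dimensions
(structure only in dims 1–2); uniform background points numbering 5% of the
1820 clean points (91); ground truth is one class per branch plus noise —
23 classes.  Choices the parameterisation leaves open were fixed once:

- Radial spacing is the length-normalised exponential
  r_i = L·(G^{i/n} − 1)/(G − 1) with total growth factor G = 2, so the
  radial density profile is independent of the per-branch point count and
  decreases monotonically outwards (local spacing doubles from centre to
  tip).  A per-point geometric factor was rejected because its concentration
  explodes with the point count, emptying the long branches.
- Star centres sit on a grid with spacing three times the maximum branch
  length, guaranteeing inter-star gaps dominate intra-star scales.
- Background points are uniform over the clean bounding box expanded by
  150% of its range per side, emulating widely scattered outliers.  A tight
  box concentrates outliers inside star hulls, where — once absorbed into a
  cluster — they bridge adjacent arms in the approximation graph and fuse
  branches.
- All randomness flows from one seed through spawned child streams (one per
  star plus one for the background), so per-star draws are independent.

What the generator does *not* emulate: unequal branch lengths within a
star, curved or crossing branches, branch-dependent noise, and the
cluster-count ambiguity of real single-cell data.  Passing the benchmark
therefore shows that connected branch structures of realistic density
contrast are recovered in the presence of moderate background noise — not
that the method resolves arbitrarily faint or entangled flares.

The random-walk generator (scaling studies) samples c uniform starting
points in a hypercube sized to fit five times the intended cluster count
(side 2·(5c)^{1/d}), then five 50-step walks per start; each step perturbs
one uniformly chosen coordinate by N(0, 0.1), and every step position is a
data point.

## Benchmark and problem sizes

The star benchmark runs the fixed grid-search optima: flare-sensitive
clustering with core graph, leaf selection, k=6, m_c=70, m_b=10, and the
cluster-only baseline with EOM, k=2, m_c=20 (2-D column; the 8-D/16-D
columns ship in `flasc.evaluation` as well).  Scores are ARI against the
23-class ground truth with noise as an ordinary class.  The shipped
acceptance run uses five datasets of 1,911 points each — the full benchmark
scale — and completes in a few seconds on one CPU; dense N×N matrices and a
dense Prim MST are deliberate choices at this scale (N ≲ 10⁴).

## Known limitations

- Dense O(N²) memory in the distance and mutual-reachability matrices;
  spatial-index acceleration is out of scope here.
- Only the Euclidean metric is exercised by the benchmarks, though any
  scikit-learn metric name or callable is accepted.
- The centroid-based eccentricity inherits the U-vs-Y ambiguity above;
  geodesic eccentricity variants are not implemented.
- Approximate MSTs and nearest-neighbour-descent back ends are non-goals.
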