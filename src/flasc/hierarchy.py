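"""Condensed hierarchies: minimum-size condensation, stability, cluster selection.

The same machinery serves two filtrations:

* sublevel (density): single-linkage merges at mutual-reachability distances
  ``h`` are tracked on the density scale ``lambda = 1/h``; components appear
  at density maxima and merge as ``lambda`` decreases.
* superlevel (eccentricity): per-cluster graph edges weighted by the
  eccentricity of their least eccentric endpoint are processed in decreasing
  order; branches appear at eccentricity maxima (branch tips) and merge
  towards the cluster centre.

Internally both are join trees processed from high to low filtration value.
A *condensed* tree keeps a segment alive through merges that only attach
fewer than ``min_size`` points ("falling out of the parent") and records a
true split only where at least two merging components carry ``min_size``
points each.  Simultaneous equal-value merge events are treated as a single
multi-way event, so a point whose own filtration value coincides with the
merge of the surrounding components exits the *parent* segment rather than
being attributed to an arbitrary side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import (
    CoreDistanceTable,
    Dendrogram,
    EdgeList,
    UnionFind,
    build_mst,
    compute_core_distances,
    distance_matrix,
    mutual_reachability_matrix,
    single_linkage,
    validate_points,
)

SUBLEVEL = "sublevel"
SUPERLEVEL = "superlevel"


@dataclass
class CondensedTree:
    """Simplified merge hierarchy on an internal monotone filtration scale.

    Entries form an edge list: ``child`` (a point id ``< n_points`` or a
    segment id ``>= n_points``) leaves/enters ``parent`` at ``value``.
    Values are stored on a scale that *increases* away from the root:
    ``lambda = 1/distance`` for the sublevel orientation and raw eccentricity
    for the superlevel orientation.  The root segment has id ``n_points`` and
    birth value 0; further segments are numbered breadth-first from the root.
    """

    parent: np.ndarray
    child: np.ndarray
    value: np.ndarray
    child_size: np.ndarray
    n_points: int
    orientation: str = SUBLEVEL

    @property
    def root(self) -> int:
        return self.n_points

    @property
    def _segment_entry_mask(self) -> np.ndarray:
        return self.child >= self.n_points

    def segment_ids(self) -> np.ndarray:
        segs = np.concatenate(([self.root], self.child[self._segment_entry_mask]))
        return np.unique(segs)

    def segment_children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {int(s): [] for s in self.segment_ids()}
        mask = self._segment_entry_mask
        for p, c in zip(self.parent[mask], self.child[mask]):
            out[int(p)].append(int(c))
        return out

    def leaves(self) -> list[int]:
        children = self.segment_children()
        return sorted(s for s, cs in children.items() if not cs)

    def births(self) -> dict[int, float]:
        """Filtration value at which each segment is created; 0 for the root."""
        out = {int(self.root): 0.0}
        mask = self._segment_entry_mask
        for c, v in zip(self.child[mask], self.value[mask]):
            out[int(c)] = float(v)
        return out

    def deaths(self) -> dict[int, float]:
        """Largest filtration value among each segment's direct entries."""
        out = {int(s): 0.0 for s in self.segment_ids()}
        for p, v in zip(self.parent, self.value):
            p = int(p)
            if v > out[p]:
                out[p] = float(v)
        return out

    def subtree_maxima(self) -> dict[int, float]:
        """Largest filtration value anywhere in each segment's subtree."""
        out = self.deaths()
        parent_of = self.segment_parents()
        # ids are topological (parent < child): one reverse sweep suffices
        for s in sorted(out, reverse=True):
            p = parent_of.get(s)
            if p is not None and out[s] > out[p]:
                out[p] = out[s]
        return out

    def segment_parents(self) -> dict[int, int | None]:
        out: dict[int, int | None] = {int(self.root): None}
        mask = self._segment_entry_mask
        for p, c in zip(self.parent[mask], self.child[mask]):
            out[int(c)] = int(p)
        return out

    def segment_sizes(self) -> dict[int, int]:
        sizes = {int(self.root): int(np.sum(self.child < self.n_points))}
        # root size = all points that ever exit anywhere
        sizes[int(self.root)] = int(np.sum(~self._segment_entry_mask))
        mask = self._segment_entry_mask
        for c, s in zip(self.child[mask], self.child_size[mask]):
            sizes[int(c)] = int(s)
        return sizes

    def point_exits(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(points, segments, exit values); every point appears exactly once."""
        mask = ~self._segment_entry_mask
        return self.child[mask], self.parent[mask], self.value[mask]

    def point_exit_values(self) -> np.ndarray:
        pts, _, vals = self.point_exits()
        out = np.full(self.n_points, np.nan)
        out[pts] = vals
        return out

    def point_exit_segments(self) -> np.ndarray:
        pts, segs, _ = self.point_exits()
        out = np.full(self.n_points, -1, dtype=np.intp)
        out[pts] = segs
        return out

    # -- serialisation -----------------------------------------------------

    def to_dict(self, point_ids: np.ndarray | None = None, include_persistence: bool = False) -> dict:
        """JSON-ready document.

        Segment births/deaths are reported on the orientation's natural
        scale: for the sublevel orientation birth <= death in ``lambda``
        terms; for the superlevel orientation a branch is born at its largest
        eccentricity and dies where it merges, so birth >= death.
        """
        births = self.births()
        tops = self.subtree_maxima()
        sizes = self.segment_sizes()
        parents = self.segment_parents()
        segments = []
        for s in sorted(births):
            if self.orientation == SUPERLEVEL:
                birth, death = tops[s], births[s]
            else:
                birth, death = births[s], tops[s]
            rec = {
                "id": int(s),
                "parent": int(parents[s]) if parents[s] is not None else int(s),
                "birth": float(birth),
                "death": float(death),
                "size": int(sizes[s]),
            }
            if include_persistence:
                rec["persistence"] = float(tops[s] - births[s])
            segments.append(rec)
        pts, segs, vals = self.point_exits()
        if point_ids is None:
            point_ids = np.arange(self.n_points)
        exits = [
            {"point": int(point_ids[p]), "parent": int(s), "exit_value": float(v)}
            for p, s, v in sorted(zip(pts.tolist(), segs.tolist(), vals.tolist()))
        ]
        return {
            "orientation": self.orientation,
            "n_points": int(self.n_points),
            "segments": segments,
            "point_exits": exits,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(**kwargs), indent=1)


def _condense_union(
    u: np.ndarray,
    v: np.ndarray,
    values: np.ndarray,
    n: int,
    min_size: int,
    orientation: str,
) -> CondensedTree:
    """Condense a filtration given merge edges on the monotone value scale.

    Edges are processed in decreasing ``values`` order; equal values form one
    multi-way event.  Raises on disconnected input.
    """
    if min_size < 2:
        raise ValueError(f"min_size must be >= 2, got {min_size}")
    if n < 1:
        raise ValueError("empty input")

    ep: list[int] = []  # entry parents (provisional segment ids)
    ec: list[int] = []  # entry children (points or provisional segment ids)
    ev: list[float] = []
    es: list[int] = []

    uf = UnionFind(n)
    size_of = np.ones(n, dtype=np.intp)
    seg_of: dict[int, int] = {}  # component root -> open segment id
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_seg = n  # provisional; renumbered breadth-first below

    order = np.lexsort((v, u, -values))
    u, v, values = u[order], v[order], values[order]
    n_edges = len(values)
    n_unions = 0
    last_value = np.nan

    i = 0
    while i < n_edges:
        j = i
        val = values[i]
        while j < n_edges and values[j] == val:
            j += 1
        # group this batch's edges by the pre-batch components they touch
        pairs = []
        for e in range(i, j):
            ru, rv = uf.find(int(u[e])), uf.find(int(v[e]))
            if ru != rv:
                pairs.append((ru, rv))
        if pairs:
            last_value = float(val)
        # local union-find over involved roots to find multi-way groups
        local: dict[int, int] = {}

        def lfind(x: int) -> int:
            r = x
            while local.get(r, r) != r:
                r = local[r]
            while local.get(x, x) != r:
                local[x], x = r, local[x]
            return r

        groups: dict[int, list[int]] = {}
        for a, b in pairs:
            ra, rb = lfind(a), lfind(b)
            if ra != rb:
                local[rb] = ra
        for a, b in pairs:
            groups.setdefault(lfind(a), [])
        for root in {lfind(a) for a, b in pairs} | {lfind(b) for a, b in pairs}:
            groups.setdefault(root, [])
        seen: set[int] = set()
        for a, b in pairs:
            for r in (a, b):
                if r not in seen:
                    seen.add(r)
                    groups[lfind(r)].append(r)

        for parts in groups.values():
            if len(parts) < 2:
                continue
            big = [p for p in parts if p in seg_of]
            total = int(sum(size_of[p] for p in parts))
            part_members = [members.pop(p, None) for p in parts]
            part_sizes = [int(size_of[p]) for p in parts]
            part_segs = [seg_of.pop(p, None) for p in parts]
            # merge in the main union-find
            r = parts[0]
            for p in parts[1:]:
                r = uf.union(r, p)
            size_of[r] = total
            n_unions += len(parts) - 1

            if total < min_size:
                merged: list[int] = []
                for m in part_members:
                    merged.extend(m)
                members[r] = merged
            elif not big:
                seg = next_seg
                next_seg += 1
                for m in part_members:
                    for pt in m:
                        ep.append(seg)
                        ec.append(pt)
                        ev.append(float(val))
                        es.append(1)
                seg_of[r] = seg
            elif len(big) == 1:
                seg = part_segs[[k for k, s in enumerate(part_segs) if s is not None][0]]
                for m in part_members:
                    if m is None:
                        continue
                    for pt in m:
                        ep.append(seg)
                        ec.append(pt)
                        ev.append(float(val))
                        es.append(1)
                seg_of[r] = seg
            else:
                parent = next_seg
                next_seg += 1
                for k, s in enumerate(part_segs):
                    if s is not None:
                        ep.append(parent)
                        ec.append(s)
                        ev.append(float(val))
                        es.append(part_sizes[k])
                    else:
                        for pt in part_members[k]:
                            ep.append(parent)
                            ec.append(pt)
                            ev.append(float(val))
                            es.append(1)
                seg_of[r] = parent
        i = j

    if n_unions != n - 1:
        raise ValueError("input is disconnected: filtration does not produce a single root")

    root_comp = uf.find(0)
    if root_comp not in seg_of:
        # never reached min_size: everything exits a lone root segment at the
        # final merge value (or, for a single point, at value 0)
        seg = next_seg
        next_seg += 1
        val = last_value if np.isfinite(last_value) or n > 1 else 0.0
        if n == 1:
            val = 0.0
        for pt in members.pop(root_comp):
            ep.append(seg)
            ec.append(pt)
            ev.append(float(val))
            es.append(1)
        seg_of[root_comp] = seg

    return _renumber(
        np.asarray(ep, dtype=np.intp),
        np.asarray(ec, dtype=np.intp),
        np.asarray(ev, dtype=np.float64),
        np.asarray(es, dtype=np.intp),
        n,
        int(seg_of[root_comp]),
        orientation,
    )


def _renumber(
    parent: np.ndarray,
    child: np.ndarray,
    value: np.ndarray,
    child_size: np.ndarray,
    n: int,
    root_prov: int,
    orientation: str,
) -> CondensedTree:
    """Relabel provisional segment ids breadth-first from the root (root = n)."""
    kids: dict[int, list[int]] = {}
    for p, c in zip(parent, child):
        if c >= n:
            kids.setdefault(int(p), []).append(int(c))
    mapping = {root_prov: n}
    queue = [root_prov]
    nxt = n + 1
    while queue:
        node = queue.pop(0)
        for c in sorted(kids.get(node, [])):
            mapping[c] = nxt
            nxt += 1
            queue.append(c)
    new_parent = np.array([mapping[int(p)] for p in parent], dtype=np.intp)
    new_child = np.array(
        [mapping[int(c)] if c >= n else int(c) for c in child], dtype=np.intp
    )
    order = np.lexsort((new_child, new_parent))
    return CondensedTree(
        parent=new_parent[order],
        child=new_child[order],
        value=value[order],
        child_size=child_size[order],
        n_points=n,
        orientation=orientation,
    )


def condense(dendrogram: Dendrogram, min_size: int, orientation: str = SUBLEVEL) -> CondensedTree:
    """Condense a single-linkage dendrogram under a minimum segment size.

    For the sublevel orientation merge heights ``h`` become
    ``lambda = 1/h`` (``+inf`` for zero-height merges, which are therefore
    processed first: duplicate points are inseparable).  For the superlevel
    orientation heights are used as-is and processed in decreasing order.
    """
    n = dendrogram.n_points
    if n == 1:
        return _condense_union(
            np.empty(0, np.intp), np.empty(0, np.intp), np.empty(0), 1, min_size, orientation
        )
    # Represent each merge by an edge between one representative point of
    # either side, so the dendrogram and edge-based paths share one engine.
    rep = np.arange(2 * n - 1, dtype=np.intp)
    for t in range(len(dendrogram)):
        rep[n + t] = rep[dendrogram.left[t]]
    eu = np.minimum(rep[dendrogram.left], rep[dendrogram.right])
    ev_ = np.maximum(rep[dendrogram.left], rep[dendrogram.right])
    if orientation == SUBLEVEL:
        with np.errstate(divide="ignore"):
            vals = np.where(dendrogram.height > 0, 1.0 / np.where(dendrogram.height > 0, dendrogram.height, 1.0), np.inf)
    elif orientation == SUPERLEVEL:
        vals = np.asarray(dendrogram.height, dtype=np.float64)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return _condense_union(eu, ev_, vals, n, min_size, orientation)


def compute_stabilities(tree: CondensedTree) -> dict[int, float]:
    """Per-segment stability: the sum over member points of the filtration
    range during which they belong to the segment (points that continue into
    child segments contribute up to the split)."""
    births = tree.births()
    out = {s: 0.0 for s in births}
    for p, v, s in zip(tree.parent, tree.value, tree.child_size):
        out[int(p)] += (float(v) - births[int(p)]) * int(s)
    return out


@dataclass
class SelectionResult:
    """Flat labels and membership probabilities for one segment selection."""

    labels: np.ndarray
    probabilities: np.ndarray
    selected: np.ndarray
    stabilities: dict[int, float]
    tree: CondensedTree = field(repr=False, default=None)

    @property
    def n_clusters(self) -> int:
        return len(self.selected)


def _bfs_segments(children: dict[int, list[int]], start: int) -> list[int]:
    out, queue = [], [start]
    while queue:
        node = queue.pop(0)
        out.append(node)
        queue.extend(children.get(node, []))
    return out


def _epsilon_search(
    leaves: set[int],
    tree: CondensedTree,
    epsilon: float,
    allow_single: bool,
) -> set[int]:
    """Merge selected segments born at distance < epsilon into the first
    ancestor born at distance >= epsilon (the root only if allowed)."""
    births = tree.births()
    parents = tree.segment_parents()
    children = tree.segment_children()
    root = tree.root
    selected: list[int] = []
    processed: set[int] = set()

    def birth_distance(seg: int) -> float:
        lam = births[seg]
        return np.inf if lam == 0 else 1.0 / lam

    for leaf in sorted(leaves):
        if birth_distance(leaf) >= epsilon:
            selected.append(leaf)
            continue
        if leaf in processed:
            continue
        node = leaf
        while True:
            parent = parents[node]
            if parent == root:
                node = parent if allow_single else node
                break
            if birth_distance(parent) > epsilon:
                node = parent
                break
            node = parent
        selected.append(node)
        processed.update(_bfs_segments(children, node))
    return set(selected)


def _select(
    tree: CondensedTree,
    method: str = "eom",
    allow_single: bool = False,
    selection_epsilon: float = 0.0,
    zero_label_single: bool = False,
    max_segment_size: int | None = None,
) -> SelectionResult:
    if method not in ("eom", "leaf"):
        raise ValueError(f"unknown selection method {method!r}")
    if selection_epsilon < 0:
        raise ValueError("selection_epsilon must be non-negative")
    if selection_epsilon > 0 and tree.orientation != SUBLEVEL:
        raise ValueError(
            "selection_epsilon is a distance threshold and applies to sublevel "
            "(density) trees; use simplify_persistence for superlevel trees"
        )

    n = tree.n_points
    root = tree.root
    stab = compute_stabilities(tree)
    children = tree.segment_children()
    sizes = tree.segment_sizes()
    node_list = sorted(stab, reverse=True)
    if not allow_single:
        node_list = [s for s in node_list if s != root]

    selected: set[int] = set()
    if method == "eom":
        is_cluster = {s: True for s in node_list}
        running = dict(stab)
        if max_segment_size is None:
            max_segment_size = n + 1
        for node in node_list:
            subtree = sum(running[c] for c in children.get(node, []))
            if subtree > running[node] or sizes[node] > max_segment_size:
                is_cluster[node] = False
                running[node] = subtree
            else:
                for sub in _bfs_segments(children, node):
                    if sub != node:
                        is_cluster[sub] = False
        selected = {s for s, flag in is_cluster.items() if flag}
        if selection_epsilon > 0 and len(children.get(root, [])) > 0:
            if not (len(selected) == 1 and root in selected):
                selected = _epsilon_search(selected, tree, selection_epsilon, allow_single)
    else:
        leaves = set(tree.leaves())
        if selection_epsilon > 0 and leaves != {root}:
            selected = _epsilon_search(leaves, tree, selection_epsilon, allow_single)
        else:
            selected = leaves

    selected_sorted = np.array(sorted(selected), dtype=np.intp)
    label_of = {int(s): i for i, s in enumerate(selected_sorted)}

    # resolve each point's exit segment to its nearest selected ancestor
    parents = tree.segment_parents()
    resolve: dict[int, int | None] = {}

    def resolve_segment(seg: int) -> int | None:
        path = []
        node: int | None = seg
        while node is not None and node not in resolve:
            if node in selected:
                resolve[node] = node
                break
            path.append(node)
            node = parents[node]
        anchor = resolve.get(node) if node is not None else None
        for s in path:
            resolve[s] = anchor
        return resolve.get(seg)

    exit_seg = tree.point_exit_segments()
    exit_val = tree.point_exit_values()
    labels = np.full(n, -1, dtype=np.intp)
    root_selected = root in selected

    if root_selected:
        # a selected root implies it is the only selection
        if zero_label_single and allow_single and selection_epsilon == 0.0:
            labels[:] = 0
        elif allow_single:
            if selection_epsilon > 0:
                threshold = 1.0 / selection_epsilon
            else:
                root_vals = tree.value[tree.parent == root]
                threshold = root_vals.max() if len(root_vals) else 0.0
            labels[exit_val >= threshold] = 0
        # allow_single False (leaf fallback): everything stays noise
    else:
        for p in range(n):
            anchor = resolve_segment(int(exit_seg[p]))
            if anchor is not None:
                labels[p] = label_of[anchor]

    probabilities = membership_probabilities(tree, selected_sorted, labels)
    return SelectionResult(
        labels=labels,
        probabilities=probabilities,
        selected=selected_sorted,
        stabilities=stab,
        tree=tree,
    )


def select_eom(
    tree: CondensedTree,
    allow_single: bool = False,
    selection_epsilon: float = 0.0,
    zero_label_single: bool = False,
) -> SelectionResult:
    """Excess-of-mass selection: bottom-up, a segment is kept when its own
    stability is at least the propagated stability of its subtree; no two
    selected segments overlap and the root is eligible only when allowed."""
    return _select(tree, "eom", allow_single, selection_epsilon, zero_label_single)


def select_leaf(
    tree: CondensedTree,
    selection_epsilon: float = 0.0,
    allow_single: bool = False,
    zero_label_single: bool = False,
) -> SelectionResult:
    """Select all leaf segments (after optional epsilon merging)."""
    return _select(tree, "leaf", allow_single, selection_epsilon, zero_label_single)


def membership_probabilities(
    tree: CondensedTree, selected: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Per-point membership: the point's exit value over the largest exit
    value among the selected segment's direct entries, clamped to [0, 1].
    Noise points get 0."""
    n = tree.n_points
    probs = np.zeros(n, dtype=np.float64)
    if len(selected) == 0:
        return probs
    deaths = tree.deaths()
    exit_val = tree.point_exit_values()
    for p in range(n):
        lab = labels[p]
        if lab < 0:
            continue
        death = deaths[int(selected[lab])]
        v = exit_val[p]
        if death == 0.0 or np.isinf(v):
            probs[p] = 1.0
        else:
            probs[p] = min(v, death) / death
    return probs


def simplify_persistence(tree: CondensedTree, persistence_threshold: float) -> CondensedTree:
    """Merge leaves whose persistence (subtree maximum minus birth, on the
    tree's internal scale) is below the threshold into their parents, until
    every remaining leaf meets the threshold.

    When a dissolved leaf leaves its parent with a single remaining segment
    child, that child is spliced into the parent (the split no longer exists).
    Segment ids are preserved (a subset of the input ids).
    """
    if persistence_threshold < 0:
        raise ValueError("persistence threshold must be non-negative")
    if persistence_threshold == 0:
        return tree
    parent = tree.parent.copy()
    child = tree.child.copy()
    value = tree.value.copy()
    child_size = tree.child_size.copy()
    n = tree.n_points
    root = tree.root

    def current() -> CondensedTree:
        return CondensedTree(parent, child, value, child_size, n, tree.orientation)

    while True:
        t = current()
        births = t.births()
        tops = t.subtree_maxima()
        kids = t.segment_children()
        leaves = [s for s in t.leaves() if s != root]
        weak = [(tops[s] - births[s], s) for s in leaves if tops[s] - births[s] < persistence_threshold]
        if not weak:
            return t
        _, leaf = min(weak)
        par = t.segment_parents()[leaf]
        # dissolve the leaf into its parent
        keep = ~((child == leaf) & (parent == par))
        parent, child, value, child_size = parent[keep], child[keep], value[keep], child_size[keep]
        parent[parent == leaf] = par
        siblings = [c for c in kids[par] if c != leaf]
        if len(siblings) == 1:
            # the split disappears: splice the lone sibling into the parent
            sib = siblings[0]
            keep = ~((child == sib) & (parent == par))
            parent, child, value, child_size = parent[keep], child[keep], value[keep], child_size[keep]
            parent[parent == sib] = par


# ---------------------------------------------------------------------------
# full density pipeline


def _density_stage(
    X: np.ndarray,
    min_samples: int,
    min_cluster_size: int,
    metric: str | callable = "euclidean",
) -> dict:
    """Shared first stage: distances, cores, MST, condensed density tree."""
    X = validate_points(X)
    dists = distance_matrix(X, metric)
    cores = compute_core_distances(X, min_samples, metric, dists=dists)
    mreach = mutual_reachability_matrix(dists, cores)
    mst = build_mst(None, cores, mreach=mreach)
    n = X.shape[0]
    if n == 1:
        tree = _condense_union(
            np.empty(0, np.intp), np.empty(0, np.intp), np.empty(0), 1, min_cluster_size, SUBLEVEL
        )
    else:
        with np.errstate(divide="ignore"):
            vals = np.where(mst.w > 0, 1.0 / np.where(mst.w > 0, mst.w, 1.0), np.inf)
        tree = _condense_union(mst.u, mst.v, vals, n, min_cluster_size, SUBLEVEL)
    return {"X": X, "dists": dists, "cores": cores, "mreach": mreach, "mst": mst, "tree": tree}


def flat_clusters(
    X: np.ndarray,
    min_samples: int = 5,
    min_cluster_size: int = 25,
    cluster_selection_method: str = "eom",
    allow_single_cluster: bool = False,
    cluster_selection_epsilon: float = 0.0,
    metric: str | callable = "euclidean",
) -> SelectionResult:
    """HDBSCAN*-style flat clustering: cores -> MST -> condensed tree -> selection.

    When a single cluster is allowed and selected and the selection epsilon is
    unused, *all* points receive label 0 (no noise), so branching structure in
    single-cluster data remains analysable.
    """
    if min_cluster_size < 2:
        raise ValueError(f"min_cluster_size must be >= 2, got {min_cluster_size}")
    stage = _density_stage(X, min_samples, min_cluster_size, metric)
    return _select(
        stage["tree"],
        method=cluster_selection_method,
        allow_single=allow_single_cluster,
        selection_epsilon=cluster_selection_epsilon,
        zero_label_single=True,
    )
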