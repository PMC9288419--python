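"""Recent-vertex forests, the component-count step function, and branching
values — the combinatorial skeleton behind maxPD-set characterisation.

On a clock-like tree, read time as running down the page: leaves sit in the
present and a vertex at height h lived h units ago.  For a look-back depth
d >= 0, the *recent* vertices R(d) are those within d of the present, and
T[R(d)] is the forest the tree induces on them.  As d grows, components
merge; the component count c(d) is a non-increasing step function with
c(0) = n and c(root height) = 1.

An integer k is a *branching value* when c(d) = k for some d, and the
*branching distance* d_k is the smallest such d.  Simultaneous merges (ties
in vertex heights) make some counts unattainable, so not every k in [1, n]
is a branching value; 1 and n always are.  For any k, ``bracket`` returns
the nearest branching values (k-, k+) with k- <= k <= k+.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .errors import InvalidSizeError, PDSetsError
from .tree_io import RootedPhyloTree, UltrametricHeights, all_clusters

__all__ = [
    "ComponentPartition",
    "BranchingProfile",
    "recent_forest",
    "branching_profile",
    "bracket",
]


@dataclass
class ComponentPartition:
    """The components of T[R(d)], each reported by its leaf-label set.

    Components are sorted lexicographically by their smallest member, so
    printed partitions are reproducible.
    """

    d: float
    components: list  # list of frozensets of leaf labels
    leaf_counts: list  # parallel list of ints

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass
class BranchingProfile:
    """c(d) evaluated at every merge height, with d_k per branching value."""

    branching_values: list  # sorted ints, always containing 1 and n
    branching_distance: dict  # k -> d_k
    component_partition: dict  # k -> ComponentPartition at d_k


def _component_roots(tree: RootedPhyloTree, height: list, d: float,
                     eps: float) -> list:
    """Vertices that head a component of T[R(d)]: recent vertices whose
    parent is absent or not recent."""
    roots = []
    for v in range(tree.n_vertices):
        if height[v] <= d + eps:
            p = tree.parent[v]
            if p is None or height[p] > d + eps:
                roots.append(v)
    return roots


def recent_forest(tree: RootedPhyloTree, heights: UltrametricHeights,
                  d: float) -> ComponentPartition:
    """Partition the leaf set by the components of T[R(d)]."""
    if d < 0:
        raise PDSetsError(f"look-back depth must be non-negative, got {d}")
    eps = heights.tolerance
    clus = all_clusters(tree)
    comps = [clus[v] for v in _component_roots(tree, heights.height, d, eps)]
    comps.sort(key=min)
    return ComponentPartition(d=d, components=comps,
                              leaf_counts=[len(c) for c in comps])


def branching_profile(tree: RootedPhyloTree,
                      heights: UltrametricHeights) -> BranchingProfile:
    """Evaluate c(d) at every distinct vertex height and record, for each
    attained component count k, the minimal height as the branching
    distance d_k.

    Heights equal within tolerance are grouped into one merge event, which
    is what makes intermediate counts skippable.
    """
    eps = heights.tolerance
    h = heights.height
    # distinct heights, grouped within eps (heights are sorted first)
    distinct: list = []
    for x in sorted(h):
        if not distinct or x - distinct[-1] > eps:
            distinct.append(x)
    values: list = []
    dist: dict = {}
    parts: dict = {}
    for d in distinct:
        part = recent_forest(tree, heights, d)
        k = part.n_components
        if k not in dist:  # first (minimal) height attaining this count
            dist[k] = d
            parts[k] = part
            values.append(k)
    values.sort()
    return BranchingProfile(branching_values=values, branching_distance=dist,
                            component_partition=parts)


def bracket(profile: BranchingProfile, k: int):
    """The nearest branching values (k-, k+) around k, with k- <= k <= k+."""
    vals = profile.branching_values
    n = vals[-1]
    if not 1 <= k <= n:
        raise InvalidSizeError(f"k must be in [1, {n}], got {k}")
    i = bisect.bisect_right(vals, k)
    k_minus = vals[i - 1]
    k_plus = k_minus if k_minus == k else vals[i]
    return k_minus, k_plus
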