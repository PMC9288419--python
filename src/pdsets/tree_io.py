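"""Rooted edge-weighted phylogenetic trees: parsing, validation, queries.

The central object is :class:`RootedPhyloTree`, a lightweight rooted tree
with strictly positive edge lengths and uniquely labelled leaves.  Newick
reading/writing is delegated to :mod:`dendropy`; the class itself stores a
flat parent/children representation that the diversity algorithms traverse
directly.

Edge lengths are interpreted as amounts of evolution (typically time).  A
tree is *ultrametric* (clock-like) when every leaf lies at the same distance
from the root; :func:`ultrametric_heights` validates this and returns the
per-vertex height above the present, which the component machinery in
:mod:`pdsets.components` relies on.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy

from .errors import NotUltrametricError, TreeFormatError, UnknownLabelError

__all__ = [
    "RootedPhyloTree",
    "UltrametricHeights",
    "parse_newick",
    "write_newick",
    "ultrametric_heights",
    "cluster",
]


@dataclass
class RootedPhyloTree:
    """A rooted phylogenetic tree with positive edge lengths.

    Vertices are integers ``0..len(parent)-1``; the root is vertex ``0``.
    ``edge_length[v]`` is the length of the edge above ``v`` (``None`` for
    the root).  ``label[v]`` is the taxon name for leaves, ``None``
    otherwise.  Every non-leaf, non-root vertex has out-degree >= 2; the
    single-vertex tree (one labelled leaf, no edges) is allowed.
    """

    parent: list  # vertex -> parent vertex id, None at root
    children: list  # vertex -> list of child ids (canonical order)
    edge_length: list  # vertex -> length of edge above it, None at root
    label: list  # vertex -> leaf label or None
    root: int = 0
    _leaf_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._leaf_index:
            self._leaf_index = {
                lab: v for v, lab in enumerate(self.label) if lab is not None
            }

    # -- basic queries -----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_index)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def leaves(self) -> list:
        """Leaf vertex ids, sorted lexicographically by label."""
        return [self._leaf_index[lab] for lab in self.leaf_labels()]

    def leaf_labels(self) -> list:
        """All leaf labels, sorted lexicographically."""
        return sorted(self._leaf_index)

    def leaf_vertex(self, label: str) -> int:
        try:
            return self._leaf_index[label]
        except KeyError:
            raise UnknownLabelError(f"unknown leaf label: {label!r}") from None

    def has_leaf(self, label: str) -> bool:
        return label in self._leaf_index

    def postorder(self) -> Iterator[int]:
        """Vertices with every child before its parent; root last."""
        stack = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                yield v
            else:
                stack.append((v, True))
                for c in reversed(self.children[v]):
                    stack.append((c, False))

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            for c in reversed(self.children[v]):
                stack.append(c)

    def total_length(self) -> float:
        """Sum of all edge lengths: the PD of the full leaf set."""
        return sum(l for l in self.edge_length if l is not None)

    def root_to_leaf_distance(self, v: int) -> float:
        d = 0.0
        while self.parent[v] is not None:
            d += self.edge_length[v]
            v = self.parent[v]
        return d


@dataclass
class UltrametricHeights:
    """Per-vertex heights of an ultrametric tree.

    ``height[v]`` is the distance from vertex ``v`` down to any of its
    descendant leaves (0 at leaves; the root height equals the shared
    root-to-leaf distance d1).  ``tolerance`` is the absolute slack used
    when the heights were validated.
    """

    height: list
    root_height: float
    tolerance: float


def _validate_and_build(dtree: "dendropy.Tree") -> RootedPhyloTree:
    seed = dtree.seed_node
    if seed.edge.length is not None:
        warnings.warn(
            "length on the root edge is ignored (diversity is measured "
            "from the root)",
            stacklevel=3,
        )
    # suppress out-degree-1 vertices, summing lengths along the chain
    dtree.suppress_unifurcations()
    seed = dtree.seed_node

    parent: list = []
    children: list = []
    lengths: list = []
    labels: list = []

    def add(node, par):
        v = len(parent)
        parent.append(par)
        children.append([])
        labels.append(None)
        if par is None:
            lengths.append(None)
        else:
            children[par].append(v)
            length = node.edge.length
            if length is None:
                raise TreeFormatError("every non-root edge must carry a length")
            if not length > 0:
                raise TreeFormatError(
                    f"edge lengths must be strictly positive (found {length})"
                )
            lengths.append(float(length))
        if not node.child_nodes():
            name = None
            if node.taxon is not None:
                name = node.taxon.label
            elif node.label:
                name = node.label
            if not name:
                raise TreeFormatError("every leaf must carry a non-empty label")
            labels[v] = name
        return v

    order = [(seed, None)]
    index_of = {}
    while order:
        node, par = order.pop(0)
        v = add(node, par)
        index_of[node] = v
        for ch in node.child_nodes():
            order.append((ch, v))

    seen = set()
    for lab in labels:
        if lab is None:
            continue
        if lab in seen:
            raise TreeFormatError(f"duplicate leaf label: {lab!r}")
        seen.add(lab)

    # canonical child order: by smallest descendant leaf label
    tree = RootedPhyloTree(parent, children, lengths, labels)
    smallest: list = [None] * tree.n_vertices
    for v in tree.postorder():
        if tree.is_leaf(v):
            smallest[v] = labels[v]
        else:
            smallest[v] = min(smallest[c] for c in children[v])
    for v in range(tree.n_vertices):
        children[v].sort(key=lambda c: smallest[c])
    return tree


def parse_newick(text: str) -> RootedPhyloTree:
    """Parse a single rooted Newick tree.

    Unifurcations are suppressed (their edge lengths summed), a length on
    the root edge is ignored with a warning, and multifurcations are kept.

    Raises
    ------
    TreeFormatError
        On malformed Newick, a missing or non-positive edge length, or a
        duplicate/empty leaf label.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeFormatError(f"malformed Newick: {exc}") from exc
    return _validate_and_build(dtree)


def write_newick(tree: RootedPhyloTree) -> str:
    """Serialise to Newick; ``parse_newick`` of the result round-trips."""

    def render(v: int) -> str:
        if tree.is_leaf(v):
            core = tree.label[v]
        else:
            core = "(" + ",".join(render(c) for c in tree.children[v]) + ")"
        if tree.parent[v] is None:
            return core
        return f"{core}:{tree.edge_length[v]:.10g}"

    return render(tree.root) + ";"


def ultrametric_heights(
    tree: RootedPhyloTree, tolerance: float | None = None
) -> UltrametricHeights:
    """Validate the clock-like condition and return per-vertex heights.

    A vertex's height is the mean of its descendant-leaf distances; all such
    distances must agree within tolerance (default: 1e-9 relative to root
    height, floored at 1e-12 absolute).

    Raises
    ------
    NotUltrametricError
        Naming a witnessing leaf pair whose root distances disagree.
    """
    n = tree.n_vertices
    # per vertex: (min dist, argmin leaf, max dist, argmax leaf, sum, count)
    lo = [0.0] * n
    hi = [0.0] * n
    lo_leaf: list = [None] * n
    hi_leaf: list = [None] * n
    total = [0.0] * n
    count = [0] * n
    for v in tree.postorder():
        if tree.is_leaf(v):
            lo[v] = hi[v] = 0.0
            lo_leaf[v] = hi_leaf[v] = tree.label[v]
            total[v] = 0.0
            count[v] = 1
        else:
            best = None
            for c in tree.children[v]:
                l = tree.edge_length[c]
                clo, chi = lo[c] + l, hi[c] + l
                if best is None:
                    lo[v], lo_leaf[v] = clo, lo_leaf[c]
                    hi[v], hi_leaf[v] = chi, hi_leaf[c]
                    best = True
                else:
                    if clo < lo[v]:
                        lo[v], lo_leaf[v] = clo, lo_leaf[c]
                    if chi > hi[v]:
                        hi[v], hi_leaf[v] = chi, hi_leaf[c]
                total[v] += total[c] + l * count[c]
                count[v] += count[c]

    root_height = total[tree.root] / max(count[tree.root], 1)
    if tolerance is None:
        tolerance = max(1e-9 * abs(hi[tree.root]), 1e-12)
    for v in range(n):
        if hi[v] - lo[v] > tolerance:
            raise NotUltrametricError(
                lo_leaf[v], hi_leaf[v],
                tree.root_to_leaf_distance(tree.leaf_vertex(lo_leaf[v])),
                tree.root_to_leaf_distance(tree.leaf_vertex(hi_leaf[v])),
            )
    height = [total[v] / count[v] for v in range(n)]
    return UltrametricHeights(height=height, root_height=root_height,
                              tolerance=tolerance)


def cluster(tree: RootedPhyloTree, v: int) -> frozenset:
    """The set of leaf labels descended from vertex ``v``."""
    if not 0 <= v < tree.n_vertices:
        raise UnknownLabelError(f"unknown vertex id: {v}")
    out = []
    stack = [v]
    while stack:
        u = stack.pop()
        if tree.is_leaf(u):
            out.append(tree.label[u])
        else:
            stack.extend(tree.children[u])
    return frozenset(out)


def all_clusters(tree: RootedPhyloTree) -> dict:
    """Map vertex id -> frozenset of descendant leaf labels (one pass)."""
    clus: dict = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            clus[v] = frozenset([tree.label[v]])
        else:
            s = set()
            for c in tree.children[v]:
                s |= clus[c]
            clus[v] = frozenset(s)
    return clus
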