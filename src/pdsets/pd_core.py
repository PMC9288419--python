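"""Phylogenetic diversity (PD) of leaf subsets, PD loss, and the greedy
maximiser.

PD of a subset Y is Faith's rooted measure: the total length of the minimal
subtree connecting Y to the root,

    PD(Y) = sum of l(e) over edges e whose cluster intersects Y.

PD loss is the diversity forfeited if the taxa in Y go extinct:
Delta(Y) = PD(X) - PD(X - Y), also known as exclusive molecular
phylodiversity.

The greedy algorithm (add the leaf with the largest marginal gain) is
provably optimal for maximising PD at every size k thanks to the strong
exchange property of PD on rooted trees; it serves as the fast baseline the
counting machinery is checked against.  It is *not* valid for minimising
PD — see :mod:`pdsets.minpd` for the dynamic program that is.
"""

from __future__ import annotations

from typing import Iterable

from .errors import InvalidSizeError, UnknownLabelError
from .tree_io import RootedPhyloTree

__all__ = ["pd_score", "pd_loss", "greedy_maxpd"]


def _check_labels(tree: RootedPhyloTree, Y: Iterable[str]) -> list:
    out = []
    for lab in Y:
        out.append(tree.leaf_vertex(lab))  # raises UnknownLabelError
    return out


def pd_score(tree: RootedPhyloTree, Y: Iterable[str]) -> float:
    """PD of the non-empty leaf subset ``Y``: total length of the Y-subtree.

    Computed by walking each leaf's root path and summing each edge once.
    """
    verts = _check_labels(tree, Y)
    if not verts:
        raise UnknownLabelError("PD is undefined for the empty set")
    marked = set()
    total = 0.0
    for v in verts:
        while tree.parent[v] is not None and v not in marked:
            marked.add(v)
            total += tree.edge_length[v]
            v = tree.parent[v]
    return total


def pd_loss(tree: RootedPhyloTree, Y: Iterable[str]) -> float:
    """PD lost if the taxa in ``Y`` go extinct: PD(X) - PD(X - Y).

    ``Y`` may be empty (loss 0).  If Y = X the whole tree is lost and the
    loss is PD(X), by convention.
    """
    Yset = set(Y)
    _check_labels(tree, Yset)
    survivors = [lab for lab in tree.leaf_labels() if lab not in Yset]
    total = tree.total_length()
    if not survivors:
        return total
    return total - pd_score(tree, survivors)


def greedy_maxpd(tree: RootedPhyloTree, k: int):
    """Build a size-k maximum-PD set greedily; returns ``(set, score)``.

    At each step the leaf with the largest marginal PD gain is added (ties
    broken lexicographically by label).  The returned score equals the true
    maximum over all size-k subsets; the set itself is one of possibly many
    maximisers.  Works for arbitrary positive edge lengths.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise InvalidSizeError(f"k must be in [1, {n}], got {k}")
    # gain[leaf] = unmarked length on its root path; recompute lazily
    marked = [False] * tree.n_vertices
    chosen: list = []
    labels = tree.leaf_labels()
    remaining = set(labels)
    for _ in range(k):
        best_lab, best_gain = None, None
        for lab in labels:
            if lab not in remaining:
                continue
            v = tree.leaf_vertex(lab)
            g = 0.0
            while tree.parent[v] is not None and not marked[v]:
                g += tree.edge_length[v]
                v = tree.parent[v]
            if best_gain is None or g > best_gain:
                best_lab, best_gain = lab, g
        v = tree.leaf_vertex(best_lab)
        while tree.parent[v] is not None and not marked[v]:
            marked[v] = True
            v = tree.parent[v]
        chosen.append(best_lab)
        remaining.discard(best_lab)
    return frozenset(chosen), pd_score(tree, chosen)
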