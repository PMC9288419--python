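"""Minimum PD of k leaves — equivalently the maximum PD loss when n - k
leaves go extinct — by dynamic programming on the tree.

Unlike maximisation, minimising PD is *not* solved greedily: removing the
currently cheapest leaf can strand expensive interior edges.  Instead, for
every vertex v let phi_v(k) be the minimum PD of k leaves chosen inside the
pendant subtree below v (phi_v(0) = 0; a single vertex contributes 0).  At
an internal vertex with child edges e_1..e_t of lengths l_1..l_t,

    phi_v(k) = min over k_1 + ... + k_t = k of
               sum_i ( phi_{child_i}(k_i) + l_i * [k_i > 0] ),

i.e. a min-plus convolution of the child vectors, each shifted by its edge
length whenever the child is actually used.  Children are folded pairwise,
which reproduces the joint minimisation exactly (min-plus convolution is
associative) and stays polynomial for any out-degree.  The root vector
gives the answer; recording which split won at each fold lets a witnessing
minPD set be recovered by backtracking.

Ultrametricity is NOT required here — any positive edge lengths work.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidSizeError
from .pd_core import pd_loss, pd_score
from .tree_io import RootedPhyloTree

__all__ = ["MinPDTable", "minpd_table", "minpd_score", "minpd_set",
           "max_pd_loss"]

_INF = float("inf")


@dataclass
class MinPDTable:
    """Per-vertex minimum-PD vectors with backpointers.

    ``table[v][k]`` is the minimum PD of k leaves within the pendant
    subtree below v.  ``split[v]`` holds, for each fold step and k, the
    number of leaves assigned to the folded-in child, enabling exact
    recovery of one optimal set.
    """

    tree: RootedPhyloTree
    k_max: int
    table: dict  # vertex -> list of minima, index 0..min(n_v, k_max)
    split: dict  # vertex -> list (per child, after the first) of lists
    n_below: dict  # vertex -> number of leaves in its pendant subtree

    def root_vector(self) -> list:
        return self.table[self.tree.root]


def minpd_table(tree: RootedPhyloTree, k_max: int | None = None) -> MinPDTable:
    """Fill the dynamic-programming table bottom-up (root processed last)."""
    n = tree.n_leaves
    if k_max is None:
        k_max = n
    if not 0 <= k_max <= n:
        raise InvalidSizeError(f"k_max must be in [0, {n}], got {k_max}")
    table: dict = {}
    split: dict = {}
    n_below: dict = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            n_below[v] = 1
            table[v] = [0.0, 0.0][: k_max + 1]
            split[v] = []
            continue
        kids = tree.children[v]
        size = n_below[kids[0]]
        acc = _shifted(table[kids[0]], tree.edge_length[kids[0]])
        marks = []
        for c in kids[1:]:
            vec = _shifted(table[c], tree.edge_length[c])
            size += n_below[c]
            cap = min(size, k_max)
            nxt = [_INF] * (cap + 1)
            choice = [0] * (cap + 1)
            for k in range(cap + 1):
                best, best_kc = _INF, 0
                lo = max(0, k - (len(acc) - 1))
                hi = min(k, len(vec) - 1)
                for kc in range(lo, hi + 1):
                    val = acc[k - kc] + vec[kc]
                    # ties: prefer the smaller prefix load (larger kc last)
                    if val < best or (val == best and k - kc < k - best_kc):
                        best, best_kc = val, kc
                nxt[k] = best
                choice[k] = best_kc
            acc = nxt
            marks.append(choice)
        n_below[v] = size
        table[v] = acc
        split[v] = marks
    return MinPDTable(tree=tree, k_max=k_max, table=table, split=split,
                      n_below=n_below)


def _shifted(vec: list, length: float) -> list:
    """phi_child(k) + l * [k > 0] for all k."""
    return [vec[0]] + [x + length for x in vec[1:]]


def minpd_score(tree: RootedPhyloTree, k: int,
                table: MinPDTable | None = None) -> float:
    """The minimum PD over all size-k leaf subsets (k = 0 gives 0)."""
    n = tree.n_leaves
    if not 0 <= k <= n:
        raise InvalidSizeError(f"k must be in [0, {n}], got {k}")
    if table is None or table.k_max < k:
        table = minpd_table(tree, k)
    return table.root_vector()[k]


def minpd_set(tree: RootedPhyloTree, k: int,
              table: MinPDTable | None = None) -> frozenset:
    """One size-k set attaining the minimum PD, recovered by backtracking.

    Deterministic under the fold-order tie-break; its PD equals
    ``minpd_score(tree, k)`` exactly.
    """
    n = tree.n_leaves
    if not 0 <= k <= n:
        raise InvalidSizeError(f"k must be in [0, {n}], got {k}")
    if table is None or table.k_max < k:
        table = minpd_table(tree, k)
    chosen: list = []

    def recover(v: int, kv: int) -> None:
        if kv == 0:
            return
        if tree.is_leaf(v):
            chosen.append(tree.label[v])
            return
        kids = tree.children[v]
        loads = [0] * len(kids)
        remaining = kv
        for idx in range(len(kids) - 1, 0, -1):
            marks = table.split[v][idx - 1]
            kc = marks[remaining]
            loads[idx] = kc
            remaining -= kc
        loads[0] = remaining
        for c, kc in zip(kids, loads):
            recover(c, kc)

    recover(tree.root, k)
    return frozenset(chosen)


def max_pd_loss(tree: RootedPhyloTree, t: int):
    """Worst-case diversity loss if ``t`` leaves go extinct.

    Returns ``(Y, loss)`` where Y is a size-t set maximising the PD loss
    Delta(Y).  By duality the survivors X - Y form a size-(n - t) minPD
    set, so the DP above answers this directly.
    """
    n = tree.n_leaves
    if not 0 <= t <= n:
        raise InvalidSizeError(f"t must be in [0, {n}], got {t}")
    survivors = minpd_set(tree, n - t)
    Y = frozenset(set(tree.leaf_labels()) - survivors)
    return Y, pd_loss(tree, Y)
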