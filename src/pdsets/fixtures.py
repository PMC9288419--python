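"""Reference trees, random ultrametric tree generation, and brute-force
oracles.

The small named trees reproduce, with integer edge lengths, every worked
quantity the algorithms are validated against:

* ``tree_T1`` — 7 leaves; triple {x1,x2,x3} and fork {x4..x7}; PD of
  {x3,x4,x7} is 16, of {x4,x7} is 10, of {x5,x6,x7} is 11; twenty size-3
  maxPD sets.
* ``tree_T2`` — 11 leaves, binary; branching values {1,2,4,7,9,11};
  counting polynomial 16x^7 + 64x^6 + 84x^5 + 36x^4.
* ``tree_T3`` — 16 leaves whose size-8 counting polynomial is
  (x^2+2x)^2 (2x^2+3x)^4, giving 1809 size-8 maxPD sets — more than the
  perfect unit-length tree on 16 leaves achieves at its best k.
* ``tree_mammal_P`` — a 32-leaf tree realising the component structure of
  a published mammal-family phylogeny: component sizes 1,8,3,2,7,3,5,3 at
  one cut depth (15120 size-8 maxPD sets) and sixteen components at a
  shallower cut (2880 size-16 maxPD sets).

``random_ultrametric`` draws seeded coalescent-style trees, optionally
with tied merge heights (which skip branching values) and multifurcations,
to exercise exactly the structures the counting theory must handle.
``brute_force`` enumerates every size-k subset and is the independent
oracle for all optimisation and counting routines.
"""

from __future__ import annotations

import random
from itertools import combinations
from typing import Mapping, Sequence

from .errors import InvalidSizeError, PDSetsError
from .pd_core import pd_score
from .tree_io import RootedPhyloTree, parse_newick

__all__ = [
    "tree_T1", "tree_T2", "tree_T3", "tree_mammal_P",
    "perfect_tree", "caterpillar", "random_ultrametric",
    "brute_force", "FIXTURES",
]

T1_NEWICK = "(((x1:1,x2:1):3,x3:4):2,((x4:1,x5:1):3,(x6:1,x7:1):3):2);"
T2_NEWICK = ("((((x1:1,x2:1):2,x3:3):1,x4:4):1,"
             "(((x5:1,x6:1):2,(x7:2,x8:2):1):1,"
             "((x9:2,x10:2):1,x11:3):1):1);")
# six deep components finishing at height 2: two splitting 1+1, four
# splitting a singleton against a height-1 cherry
T3_NEWICK = (
    "(((((t01:2,t02:2):1,(t03:2,t04:2):1):1,"
    "(((t05:1,t06:1):1,t07:2):1,((t08:1,t09:1):1,t10:2):1):1):1,"
    "((t11:1,t12:1):1,t13:2):3):1,"
    "((t14:1,t15:1):1,t16:2):4);"
)

# deep components of the mammal structure, each a list of shallow-component
# sizes; shallow components are stars at height 1, deep merges at height 3,
# root at height 4
_MAMMAL_GROUPS = [[1], [2, 4, 1, 1], [3], [1, 1], [2, 1, 4], [3], [5],
                  [1, 1, 1]]


def tree_T1() -> RootedPhyloTree:
    """The 7-leaf example tree (heights: cherries 1, root children 4,
    root 6)."""
    return parse_newick(T1_NEWICK)


def tree_T2() -> RootedPhyloTree:
    """The 11-leaf binary example tree with skipped branching values."""
    return parse_newick(T2_NEWICK)


def tree_T3() -> RootedPhyloTree:
    """The 16-leaf tree beating the perfect tree's maxPD-set count."""
    return parse_newick(T3_NEWICK)


def tree_mammal_P() -> RootedPhyloTree:
    """A 32-leaf tree realising the mammal-family component structure.

    Only the two nested component partitions matter for the counts, so the
    fixture uses generic labels m01..m32 and the simplest heights that
    realise them (stars at height 1, group merges at 3, root at 4).
    """
    parts = []
    idx = 0

    def leaf(height_to_root: int) -> str:
        nonlocal idx
        idx += 1
        return f"m{idx:02d}:{height_to_root}"

    for group in _MAMMAL_GROUPS:
        if len(group) == 1:
            size = group[0]
            if size == 1:
                parts.append(leaf(4))
            else:
                inner = ",".join(leaf(1) for _ in range(size))
                parts.append(f"({inner}):3")
        else:
            subs = []
            for size in group:
                if size == 1:
                    subs.append(leaf(3))
                else:
                    inner = ",".join(leaf(1) for _ in range(size))
                    subs.append(f"({inner}):2")
            parts.append("(" + ",".join(subs) + "):1")
    return parse_newick("(" + ",".join(parts) + ");")


def perfect_tree(alpha: int) -> RootedPhyloTree:
    """Complete binary tree of height ``alpha``, every edge length 1."""
    if alpha < 1:
        raise InvalidSizeError("height alpha must be >= 1")
    n = 2 ** alpha
    width = len(str(n))
    labels = [f"p{i + 1:0{width}d}" for i in range(n)]

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{labels[lo]}:1"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):1"

    mid = n // 2
    return parse_newick(f"({build(0, mid)},{build(mid, n)});")


def caterpillar(n: int, heights: Sequence[float] | None = None
                ) -> RootedPhyloTree:
    """Ultrametric rooted caterpillar (exactly one cherry) on ``n`` leaves.

    ``heights`` are the strictly increasing merge heights (default
    1, 2, ..., n-1), so branching values are all of {1..n} and the minPD
    set of each size k >= 2 is unique.
    """
    if n < 2:
        raise InvalidSizeError("a caterpillar needs n >= 2 leaves")
    if heights is None:
        heights = list(range(1, n))
    heights = [float(h) for h in heights]
    if len(heights) != n - 1 or any(
            b <= a for a, b in zip(heights, heights[1:])) or heights[0] <= 0:
        raise InvalidSizeError(
            "need n - 1 strictly increasing positive merge heights")
    width = len(str(n))
    lab = [f"c{i + 1:0{width}d}" for i in range(n)]
    core = f"({lab[0]}:{heights[0]:g},{lab[1]}:{heights[0]:g})"
    for i in range(2, n):
        h_prev, h = heights[i - 2], heights[i - 1]
        core = f"({core}:{h - h_prev:g},{lab[i]}:{h:g})"
    return parse_newick(core + ";")


def random_ultrametric(n: int, seed: int, tie_prob: float = 0.0,
                       multifurcation_prob: float = 0.0) -> RootedPhyloTree:
    """Seeded coalescent-style random ultrametric tree on ``n`` leaves.

    Lineages are merged pairwise at strictly increasing event heights;
    with probability ``tie_prob`` an event reuses the previous height
    (producing simultaneous merges, hence skipped branching values), and
    with probability ``multifurcation_prob`` an event joins three lineages
    instead of two.  Identical arguments always produce the identical
    tree.  Event heights live on a quarter-unit grid, so they are exact
    binary floats and height ties are exact.
    """
    if n < 2:
        raise InvalidSizeError("need n >= 2 leaves")
    rng = random.Random(seed)
    width = len(str(n))
    active = [(f"r{i + 1:0{width}d}", 0.0) for i in range(n)]
    height = 0.0
    while len(active) > 1:
        step = rng.randint(2, 6) * 0.25  # 0.5 .. 1.5 on an exact grid
        if height > 0.0 and rng.random() < tie_prob:
            candidates = [i for i, (_, h) in enumerate(active) if h < height]
            if len(candidates) >= 2:
                step = 0.0
        new_height = height + step
        arity = 2
        if multifurcation_prob and len(active) > 2 \
                and rng.random() < multifurcation_prob:
            arity = 3
        pool = [i for i, (_, h) in enumerate(active) if h < new_height]
        arity = min(arity, len(pool))
        picked = sorted(rng.sample(pool, arity), reverse=True)
        parts = []
        for i in picked:
            sub, h = active.pop(i)
            parts.append(f"{sub}:{new_height - h:.9g}")
        active.append(("(" + ",".join(parts) + ")", new_height))
        height = new_height
    return parse_newick(active[0][0] + ";")


def brute_force(tree: RootedPhyloTree, k: int, mode: str = "max",
                phi: Mapping | None = None, limit: int = 10 ** 6):
    """Exhaustive oracle over all size-k subsets.

    Returns ``(score, optimal_sets)`` where ``optimal_sets`` lists every
    subset attaining the optimum PD (within a 1e-9 relative band for float
    lengths).  With ``phi``, returns ``(score, optimal_sets, best_phi)``
    where ``best_phi`` is the largest phi-sum among the PD-optimal sets.
    """
    import math

    labels = tree.leaf_labels()
    n = len(labels)
    if not 1 <= k <= n:
        raise InvalidSizeError(f"k must be in [1, {n}], got {k}")
    if math.comb(n, k) > limit:
        raise PDSetsError(f"instance too large: C({n},{k}) > {limit}")
    if mode not in ("max", "min"):
        raise PDSetsError(f"mode must be 'max' or 'min', got {mode!r}")
    best = None
    scored = []
    for combo in combinations(labels, k):
        s = pd_score(tree, combo)
        scored.append((s, combo))
        if best is None:
            best = s
        elif (mode == "max" and s > best) or (mode == "min" and s < best):
            best = s
    tol = 1e-9 * max(abs(best), 1.0)
    optimal = [frozenset(c) for s, c in scored if abs(s - best) <= tol]
    if phi is None:
        return best, optimal
    best_phi = max(sum(phi[lab] for lab in A) for A in optimal)
    return best, optimal, best_phi


FIXTURES = {
    "T1": tree_T1,
    "T2": tree_T2,
    "T3": tree_T3,
    "mammalP": tree_mammal_P,
}
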