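"""Characterising and counting maximum-PD subsets on ultrametric trees.

A size-k subset A maximises PD if and only if it takes at least one leaf
from every *tall* component (the components of T[R(d_{k-})]) and at most
one leaf from every *short* component (those of T[R(d_{k+})]).  When k is
itself a branching value the two forests coincide and A must take exactly
one leaf per component, so the number of maxPD sets m(T, k) is simply the
product of the component leaf counts.

For non-branching k the short components are grouped into an array C by the
tall component containing them, and m(T, k) is the coefficient of x^k in
the generating polynomial

    p_C(x) = prod_j ( -1 + prod_i (1 + n_ij * x) ),

where n_ij is the leaf count of the i-th short component inside tall
component j (the "-1" enforces "at least one leaf per tall component", the
factors "(1 + n_ij x)" encode "at most one leaf per short component, chosen
n_ij ways").  One expansion yields m(T, m) for every m in [k-, k+] at once.

All counting uses exact Python integers; the polynomial product is the
plain sequential multiplication, which is polynomial-time and exact.

Closed forms are provided for perfect unit-length trees (complete binary,
every edge length 1, n = 2^alpha leaves):

    m(T, k) = C(2^(beta-1), k - 2^(beta-1)) * 2^(2^beta + (alpha-beta-1) k)

with beta the unique integer satisfying 2^(beta-1) < k <= 2^beta, and the
k maximising m(T, k) is floor(2n/3) (joined by floor(2n/3)+1 when
n == 1 mod 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .components import BranchingProfile, bracket, branching_profile, \
    ComponentPartition
from .errors import InvalidSizeError, UnknownLabelError
from .tree_io import RootedPhyloTree, UltrametricHeights

__all__ = [
    "ComponentArray",
    "is_maxpd",
    "count_branching",
    "component_array",
    "generating_polynomial",
    "count_maxpd",
    "count_maxpd_interval",
    "perfect_tree_count",
    "optimal_k_perfect",
    "count_bounds",
]


@dataclass
class ComponentArray:
    """Short components grouped by tall component, padded rectangular.

    ``columns[j]`` lists the short-component leaf sets nested inside tall
    component j; ``sizes[i][j]`` is the leaf count of entry (i, j), with 0
    for padding.  Columns and rows are ordered lexicographically by
    smallest leaf label, so printed arrays and polynomials are
    reproducible.
    """

    columns: list  # list of list of frozensets (no padding entries)
    k_minus: int
    k_plus: int

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def n_rows(self) -> int:
        return max(len(col) for col in self.columns)

    def size_grid(self) -> list:
        """Rectangular n_ij grid (rows x columns), 0 for padding."""
        rows = self.n_rows
        grid = [[0] * self.n_columns for _ in range(rows)]
        for j, col in enumerate(self.columns):
            for i, entry in enumerate(col):
                grid[i][j] = len(entry)
        return grid


def _profile(tree, heights, profile=None) -> BranchingProfile:
    return profile if profile is not None else branching_profile(tree, heights)


def is_maxpd(tree: RootedPhyloTree, heights: UltrametricHeights,
             A: Iterable[str], profile: BranchingProfile | None = None) -> bool:
    """Membership test: does the subset ``A`` attain the maximum PD among
    all subsets of its size?

    True iff A has >= 1 leaf in every tall component and <= 1 leaf in every
    short component for the bracket of k = |A|.
    """
    A = frozenset(A)
    for lab in A:
        tree.leaf_vertex(lab)
    if not A:
        raise UnknownLabelError("the empty set has no PD score")
    prof = _profile(tree, heights, profile)
    k_minus, k_plus = bracket(prof, len(A))
    for comp in prof.component_partition[k_minus].components:
        if not comp & A:
            return False
    for comp in prof.component_partition[k_plus].components:
        if len(comp & A) > 1:
            return False
    return True


def count_branching(partition: ComponentPartition) -> int:
    """m(T, k) for a branching value k: the product of component leaf
    counts (each maxPD set picks exactly one leaf per component)."""
    out = 1
    for c in partition.leaf_counts:
        out *= c
    return out


def component_array(tree: RootedPhyloTree, heights: UltrametricHeights,
                    k: int,
                    profile: BranchingProfile | None = None) -> ComponentArray:
    """Group the short components (at d_{k+}) by the tall component
    (at d_{k-}) containing them."""
    prof = _profile(tree, heights, profile)
    k_minus, k_plus = bracket(prof, k)
    tall = prof.component_partition[k_minus].components
    short = prof.component_partition[k_plus].components
    cols = [[] for _ in tall]
    owner = {}
    for j, t in enumerate(tall):
        for lab in t:
            owner[lab] = j
    for s in short:
        cols[owner[min(s)]].append(s)
    for col in cols:
        col.sort(key=min)
    return ComponentArray(columns=cols, k_minus=k_minus, k_plus=k_plus)


def generating_polynomial(array: ComponentArray) -> dict:
    """Expand the counting polynomial of the array exactly.

    Returns a map exponent -> integer coefficient; the coefficient of x^m
    is the number of size-m maxPD sets for every m in [k-, k+].
    """
    poly = [1]  # coefficients, poly[e] = coeff of x^e
    for col in array.columns:
        colpoly = [1]
        for entry in col:
            nij = len(entry)
            # multiply by (1 + nij x)
            nxt = [0] * (len(colpoly) + 1)
            for e, c in enumerate(colpoly):
                nxt[e] += c
                nxt[e + 1] += c * nij
            colpoly = nxt
        colpoly[0] -= 1  # at least one leaf from this tall component
        nxt = [0] * (len(poly) + len(colpoly) - 1)
        for e1, c1 in enumerate(poly):
            if c1 == 0:
                continue
            for e2, c2 in enumerate(colpoly):
                nxt[e1 + e2] += c1 * c2
        poly = nxt
    return {e: c for e, c in enumerate(poly) if c != 0}


def count_maxpd_interval(tree: RootedPhyloTree, heights: UltrametricHeights,
                         k: int,
                         profile: BranchingProfile | None = None) -> dict:
    """m(T, m) for every m in the bracket interval [k-, k+] of k.

    A single polynomial expansion answers the whole interval; for a
    branching k the interval is the single point {k}.
    """
    prof = _profile(tree, heights, profile)
    k_minus, k_plus = bracket(prof, k)
    if k_minus == k_plus:
        return {k: count_branching(prof.component_partition[k])}
    arr = component_array(tree, heights, k, profile=prof)
    poly = generating_polynomial(arr)
    return {m: poly.get(m, 0) for m in range(k_minus, k_plus + 1)}


def count_maxpd(tree: RootedPhyloTree, heights: UltrametricHeights, k: int,
                profile: BranchingProfile | None = None) -> int:
    """The number m(T, k) of size-k maxPD sets, exactly."""
    prof = _profile(tree, heights, profile)
    n = prof.branching_values[-1]
    if not 1 <= k <= n:
        raise InvalidSizeError(f"k must be in [1, {n}], got {k}")
    return count_maxpd_interval(tree, heights, k, profile=prof)[k]


def perfect_tree_count(alpha: int, k: int) -> int:
    """m(T, k) for the perfect unit-length tree of height ``alpha``.

    Uses the closed form; k = 1 (where the binomial form degenerates) is a
    branching value with n maxPD sets, one per leaf.
    """
    if alpha < 1:
        raise InvalidSizeError("height alpha must be >= 1")
    n = 2 ** alpha
    if not 1 <= k <= n:
        raise InvalidSizeError(f"k must be in [1, {n}], got {k}")
    if k == 1:
        return n
    beta = (k - 1).bit_length()  # unique beta with 2^(beta-1) < k <= 2^beta
    half = 2 ** (beta - 1)
    return math.comb(half, k - half) * 2 ** (2 ** beta + (alpha - beta - 1) * k)


def optimal_k_perfect(n: int) -> set:
    """The subset sizes maximising the number of maxPD sets on the perfect
    unit-length tree with ``n`` leaves (n a power of two)."""
    if n < 2 or n & (n - 1):
        raise InvalidSizeError(f"n must be a power of two >= 2, got {n}")
    k = (2 * n) // 3
    out = {k}
    if n % 3 == 1:
        out.add(k + 1)
    return out


def count_bounds(n: int, k: int):
    """Sharp bounds (n - k + 1, (n/k)^k) on m(T, k) over binary ultrametric
    trees when k is a branching value.  The lower bound is attained by
    caterpillars; the upper requires k components of equal size n/k.
    Non-branching k may exceed the upper bound."""
    if not 1 <= k <= n:
        raise InvalidSizeError(f"k must be in [1, {n}], got {k}")
    return n - k + 1, (n / k) ** k
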