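# pdsets

Phylogenetic-diversity subset analysis on rooted trees: exact counting of
maximum-PD sets, optimisation of a secondary score across them, and
worst-case PD loss under extinction.

## The problem

Phylogenetic diversity (PD) quantifies how much of the evolutionary Tree
of Life a set of species spans: for a rooted tree *T* with positive branch
lengths ℓ and a leaf subset *Y*,

    PD(Y) = Σ ℓ(e)  over edges e on a path from the root to some leaf in Y,

i.e. the total length of the minimal subtree connecting *Y* to the root.
Conservation studies routinely work with *maxPD sets* — size-*k* subsets
attaining the maximum PD — but such sets are far from unique, and their
number matters when maxPD benchmarks are compared against random species
selections. This package answers three questions for practitioners and
method developers in phylogenetics and conservation prioritisation:

1. **How many size-k maxPD sets does a tree have?**  On ultrametric
   (clock-like) trees, a subset is maxPD **iff** it contains ≥ 1 leaf from
   every component of the forest T[R(d_{k⁻})] ("tall" components) and ≤ 1
   leaf from every component of T[R(d_{k⁺})] ("short" components), where
   R(d) is the set of vertices within d of the leaves and k⁻ ≤ k ≤ k⁺ are
   the nearest *branching values* (component counts actually attained by
   some cut depth). When k is itself a branching value the count m(T,k) is
   the product of component leaf counts; otherwise it is the coefficient
   of x^k in the exact integer polynomial

       p(x) = Π_j ( −1 + Π_i (1 + n_ij x) ),

   with n_ij the size of the i-th short component inside tall component j.

2. **Among all maxPD sets, which one is best under a second criterion?**
   Given any leaf score φ: X → ℝ, a quadratic-time selection over the
   component structure returns a size-k maxPD set maximising Σ_{x∈A} φ(x).
   (Folding φ into pendant branch lengths is *not* valid — the package
   includes the broken baseline and a regression test demonstrating why.)

3. **What is the worst-case PD loss if t species go extinct?**  Minimum PD
   over size-(n−t) survivor sets is computed by a dynamic program on the
   tree (min-plus convolution of child vectors — no ultrametric assumption
   needed), with backtracking to recover a witnessing set. Greedy
   selection is provably correct for *maximising* PD but not for
   minimising it; the test suite exhibits a failing instance.

## Worked example

```python
from pdsets import (branching_profile, component_array,
                    generating_polynomial, ultrametric_heights)
from pdsets.fixtures import tree_T2

tree = tree_T2()                       # 11-leaf reference tree
heights = ultrametric_heights(tree)    # validates the clock-like condition
profile = branching_profile(tree, heights)
print(profile.branching_values)
arr = component_array(tree, heights, 5)
print(generating_polynomial(arr))
```

prints

```
[1, 2, 4, 7, 9, 11]
{4: 36, 5: 84, 6: 64, 7: 16}
```

meaning: only 6 of the 11 possible component counts are attainable by a
cut depth (simultaneous merges skip the rest); the tree has 36 maxPD sets
of size 4, 84 of size 5, 64 of size 6 and 16 of size 7 — one polynomial
expansion answers the whole bracket interval [4, 7] at once. The scripts
in `examples/` walk through each capability (counting, secondary-score
optimisation, worst-case loss) with commented output.

A thin command line mirrors the library:

```
pdsets count tree.nwk -k 5          # number of size-5 maxPD sets
pdsets profile tree.nwk             # branching values + component sizes
pdsets minpd tree.nwk -k 3 --set    # minimum PD and a witnessing set
pdsets maxloss tree.nwk -t 4        # worst-case loss for 4 extinctions
pdsets optimise tree.nwk -k 3 --scores phi.tsv
pdsets fixture T2                   # write a named reference tree
```

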