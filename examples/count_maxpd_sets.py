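"""How many species subsets of size k preserve the maximum possible
phylogenetic diversity?

Builds the 11-leaf reference tree, prints its branching structure, and
counts maxPD sets for a branching size (a plain product over components)
and a non-branching size (a generating-function coefficient, which answers
the whole bracket interval at once).
"""

from pdsets import (branching_profile, component_array, count_maxpd_interval,
                    generating_polynomial, ultrametric_heights)
from pdsets.fixtures import tree_T2

tree = tree_T2()
heights = ultrametric_heights(tree)
profile = branching_profile(tree, heights)

print("branching values:", profile.branching_values)
# -> [1, 2, 4, 7, 9, 11]; sizes 3, 5, 6, 8 and 10 are skipped because
#    merges happen simultaneously at tied heights

part4 = profile.component_partition[4]
print("components at d_4:", [sorted(c) for c in part4.components])
print("m(T,4) =", "*".join(map(str, part4.leaf_counts)), "=",
      count_maxpd_interval(tree, heights, 4)[4])
# -> 3*1*4*3 = 36: a size-4 maxPD set picks exactly one leaf per component

arr = component_array(tree, heights, 5)
print("size grid for k=5 (short components per tall component):",
      arr.size_grid())
poly = generating_polynomial(arr)
print("counting polynomial coefficients:", dict(sorted(poly.items())))
# -> {4: 36, 5: 84, 6: 64, 7: 16}: the x^m coefficient is the number of
#    size-m maxPD sets for every m between the bracketing branching
#    values 4 and 7 — one expansion answers them all
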