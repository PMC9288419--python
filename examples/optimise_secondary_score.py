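"""Pick, among ALL maximum-diversity subsets, one that is best under a
secondary per-species score (conservation value, cost-benefit ratio, ...).

Also demonstrates why the tempting shortcut — folding the score into the
pendant branch lengths and re-running the PD maximiser — gives a wrong
answer.
"""

from pdsets import (is_maxpd, maximise_linear_sum, naive_pendant_augmentation,
                    pd_score, ultrametric_heights)
from pdsets.fixtures import tree_T1

tree = tree_T1()
heights = ultrametric_heights(tree)

# cheap left clade, valuable right clade
phi = {f"x{i}": (1.0 if i <= 4 else 100.0) for i in range(1, 8)}

A, score = maximise_linear_sum(tree, heights, phi, k=3)
print("chosen set:", sorted(A), " phi-sum:", score,
      " PD:", pd_score(tree, A))
# -> phi-sum 201 and PD 16: the best score achievable WITHOUT giving up
#    any diversity (two 100-point species plus one 1-point species)

B, naive_score = naive_pendant_augmentation(tree, phi, k=3)
print("pendant-augmentation shortcut picks:", sorted(B),
      " phi-sum:", naive_score,
      " is maxPD?", is_maxpd(tree, heights, B))
# -> {x5, x6, x7} scores 300 but its PD is only 11, far below the
#    maximum 16 — the shortcut trades away diversity, which is exactly
#    what it was not allowed to do
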