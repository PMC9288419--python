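"""Worst-case scenario: if t species go extinct, how much evolutionary
history can be lost?

Runs the minimum-PD dynamic program (valid on any rooted tree with
positive branch lengths, clock-like or not) and recovers a witnessing
extinction set.
"""

from pdsets import max_pd_loss, minpd_score, minpd_set, pd_score
from pdsets.fixtures import tree_T1

tree = tree_T1()
print("total PD of the tree:", tree.total_length())  # -> 23

for k in (1, 2, 3):
    print(f"minimum PD over size-{k} subsets:", minpd_score(tree, k))
# -> 6, 7, 11: the cheapest k survivors; greedy selection would NOT find
#    these in general, the dynamic program does

survivors = minpd_set(tree, 3)
print("a size-3 minPD set:", sorted(survivors),
      " PD:", pd_score(tree, survivors))
# -> e.g. {x5, x6, x7} with PD 11

Y, loss = max_pd_loss(tree, t=4)
print("worst-case loss for 4 extinctions:", loss,
      " extinct set:", sorted(Y))
# -> 12 = 23 - 11: the complement of the minPD set above; over half the
#    tree's evolutionary history can vanish with only 4 of 7 species lost
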