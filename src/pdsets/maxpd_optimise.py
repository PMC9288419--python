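"""Optimising a secondary linear leaf score over all maxPD sets.

Conservation planning rarely uses diversity alone: each taxon may carry a
further value phi (benefit-cost ratio, threat category weight, ...), and
among the often astronomically many size-k maxPD sets one wants one whose
total phi is largest.  The component characterisation makes this easy:

1. compute the tall components (at d_{k-}) and short components (at d_{k+});
2. keep one max-phi leaf per short component (the 'potential' set P);
3. put into A one max-phi member of P per tall component;
4. fill A up to size k with the (k - k-) largest-phi leaves of P - A.

The output is always a maxPD set, and its phi-sum is maximal among all
size-k maxPD sets; phi may be negative.  The whole procedure is
quadratic-time.

The tempting shortcut of adding phi(x) to x's pendant edge and running the
greedy PD maximiser is *wrong*: the score can drag the augmented tree's
optimum onto a set that does not maximise PD on the original tree.
:func:`naive_pendant_augmentation` implements that broken baseline solely
so the failure is pinned down by a regression test.
"""

from __future__ import annotations

from typing import Mapping

from .components import BranchingProfile, bracket, branching_profile
from .errors import InvalidSizeError, UnknownLabelError
from .pd_core import greedy_maxpd
from .tree_io import RootedPhyloTree, UltrametricHeights

__all__ = ["maximise_linear_sum", "naive_pendant_augmentation", "read_scores"]


def _check_phi(tree: RootedPhyloTree, phi: Mapping) -> None:
    labels = set(tree.leaf_labels())
    missing = labels - set(phi)
    if missing:
        raise UnknownLabelError(
            f"score table missing leaves: {sorted(missing)[:5]}")
    unknown = set(phi) - labels
    if unknown:
        raise UnknownLabelError(
            f"score table has unknown leaves: {sorted(unknown)[:5]}")


def _argmax_phi(labels, phi):
    """Max-phi label; ties broken lexicographically (smallest label)."""
    return min(labels, key=lambda lab: (-phi[lab], lab))


def maximise_linear_sum(tree: RootedPhyloTree, heights: UltrametricHeights,
                        phi: Mapping, k: int,
                        profile: BranchingProfile | None = None):
    """Return ``(A, score)``: a size-k maxPD set with the largest phi-sum
    among all size-k maxPD sets, and that phi-sum."""
    _check_phi(tree, phi)
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise InvalidSizeError(f"k must be in [1, {n}], got {k}")
    prof = profile if profile is not None else branching_profile(tree, heights)
    k_minus, k_plus = bracket(prof, k)
    tall = prof.component_partition[k_minus].components
    short = prof.component_partition[k_plus].components

    # stage 2: one best leaf per short component
    potential = [_argmax_phi(comp, phi) for comp in short]
    pot_set = set(potential)
    # stage 3: one best potential leaf per tall component
    A = set()
    for comp in tall:
        A.add(_argmax_phi(comp & pot_set, phi))
    # stage 4: top up with the largest remaining potential leaves
    rest = sorted(pot_set - A, key=lambda lab: (-phi[lab], lab))
    A.update(rest[: k - k_minus])
    return frozenset(A), sum(phi[lab] for lab in A)


def naive_pendant_augmentation(tree: RootedPhyloTree, phi: Mapping, k: int):
    """The incorrect pendant-edge baseline, kept as a documented pitfall.

    Adds phi(x) to each leaf's pendant edge and greedily maximises PD on
    the augmented tree; returns ``(set, phi-sum)``.  The result need not be
    a maxPD set of the original tree.  Requires phi > -(pendant length) so
    the augmented lengths stay positive; n >= 2.
    """
    _check_phi(tree, phi)
    if tree.n_leaves < 2:
        raise InvalidSizeError("augmentation needs at least two leaves")
    aug = RootedPhyloTree(
        parent=list(tree.parent),
        children=[list(c) for c in tree.children],
        edge_length=list(tree.edge_length),
        label=list(tree.label),
        root=tree.root,
    )
    for lab, v in ((l, tree.leaf_vertex(l)) for l in tree.leaf_labels()):
        new_len = aug.edge_length[v] + phi[lab]
        if not new_len > 0:
            raise InvalidSizeError(
                f"augmented pendant length for {lab!r} is not positive")
        aug.edge_length[v] = new_len
    A, _ = greedy_maxpd(aug, k)
    return A, sum(phi[lab] for lab in A)


def read_scores(path) -> dict:
    """Read a leaf-score table: two-column TSV (label, value), '#' comments
    and an optional 'label<TAB>score' header line allowed."""
    phi = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise UnknownLabelError(
                    f"{path}:{lineno}: expected two tab-separated columns")
            lab, val = parts
            try:
                x = float(val)
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise UnknownLabelError(
                    f"{path}:{lineno}: non-numeric score {val!r}") from None
            if lab in phi:
                raise UnknownLabelError(
                    f"{path}:{lineno}: duplicate label {lab!r}")
            phi[lab] = x
    return phi
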