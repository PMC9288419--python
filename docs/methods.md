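# Methods

## Scope and model

The package operates on rooted phylogenetic trees T = (V, E) with strictly
positive edge lengths ℓ, leaves bijectively labelled by taxa X (|X| = n).
Every non-leaf, non-root vertex has out-degree ≥ 2 (unifurcations are
suppressed at parse time, summing lengths); multifurcations are accepted
throughout. The single-vertex tree (n = 1, no edges, PD = 0) is valid. A
length on the root edge of a Newick string is ignored with a warning: PD
is measured from the root, so an edge above the root never contributes.

Phylogenetic diversity of a non-empty subset Y ⊆ X is the rooted Faith
measure: the summed length of edges whose cluster intersects Y. PD loss
Δ(Y) = PD(X) − PD(X−Y) is the diversity forfeited if Y goes extinct
(Δ(X) = PD(X) by convention). PD is computed by marking each chosen leaf's
root path once — no tree surgery, O(|Y|·depth).

## Ultrametric validation

The counting and optimisation theory requires clock-like lengths: all
root-to-leaf distances equal. `ultrametric_heights` checks, at every
vertex, that descendant-leaf distances agree within a tolerance of
1e-9 × root height (absolute floor 1e-12 — lengths arrive as decimal
text in Newick, so exact equality is too strict for general input), and
reports a witnessing leaf pair on failure. A vertex's height is the mean
of its descendant-leaf distances. All bundled reference trees have integer
lengths, so their heights are exact.

## Component machinery

For a look-back depth d, the recent vertices R(d) are those within d of
some leaf; the forest T[R(d)] partitions X into components. A component is
identified by its highest vertex: recent, with a non-recent (or absent)
parent. Membership uses height ≤ d + ε with ε the validation tolerance.
The component count c(d) is non-increasing and only changes at vertex
heights, so it is evaluated only there (heights grouped within ε count as
one merge event — this is what makes intermediate counts unattainable).
For each attained count k (a *branching value*) the minimal such height is
recorded as the branching distance d_k; 1 and n are always branching
values, so the bracket (k⁻, k⁺) around any k is well defined. Components
and columns everywhere are ordered lexicographically by smallest leaf
label, a determinism convention of this package (input encodings do not
fix one).

Non-ultrametric input raises the validation error rather than silently
using leaf-specific distances; component determination without the clock
assumption is a different problem and out of scope here.

## Counting maxPD sets

A size-k subset is maxPD iff it hits every tall component (at d_{k⁻}) at
least once and every short component (at d_{k⁺}) at most once. For
branching k the two forests coincide and m(T,k) is the product of
component leaf counts. Otherwise the short components are grouped by
their containing tall component into an array, padded rectangular with
empty entries (size 0, contributing the factor 1 + 0·x = 1), and m(T,k)
is the x^k coefficient of Π_j(−1 + Π_i(1 + n_ij x)). The "−1" deletes the
empty selection within a column, enforcing "at least one per tall
component"; each factor (1 + n_ij x) encodes "at most one from this short
component, chosen n_ij ways".

All counting uses arbitrary-precision Python integers — perfect-tree
counts reach ~10^14 and beyond — and the polynomial product is plain
sequential multiplication (cubic in n, exact; no FFT, which would
introduce floats for no benefit at these sizes). One expansion yields
m(T, m) for every m in [k⁻, k⁺]; `count_maxpd_interval` exposes this.

Closed forms for perfect unit-length trees (complete binary, all edges
length 1, n = 2^α leaves): with β the unique integer satisfying
2^(β−1) < k ≤ 2^β,

    m(T,k) = C(2^(β−1), k − 2^(β−1)) · 2^(2^β + (α−β−1)k),

which reduces to (2^(α−β))^k at branching k = 2^β. The k = 1 case (where
the binomial degenerates) is served by the branching-value route: n sets,
one per leaf. The count-maximising k is ⌊2n/3⌋, joined by ⌊2n/3⌋ + 1 when
n ≡ 1 (mod 3); these are the maximisers at or above n/2 — a smaller k can
tie by complement symmetry (k = 3 vs k = 5 at n = 8), which the tests
document. For branching k on binary ultrametric trees,
n − k + 1 ≤ m(T,k) ≤ (n/k)^k; caterpillars attain the lower bound, and
non-branching k can exceed the upper (the 11-leaf reference tree has 84
size-5 sets against a bound of ≈ 51.5).

## Secondary-score optimisation

Given φ: X → ℝ (any sign), the optimiser keeps one max-φ leaf per short
component (the potential set P), adds to A one max-φ member of P per tall
component, and tops up with the (k − k⁻) largest-φ leaves of P − A. The
output is always a maxPD set and its φ-sum is maximal among all size-k
maxPD sets; ties are broken lexicographically by label (any choice is
optimal — determinism is chosen for testability). Weighted variants are
reduced by the caller via rescaling φ. The pendant-edge augmentation
shortcut is retained only as a documented incorrect baseline with a
regression test pinning its failure case.

## Minimum PD / maximum PD loss

φ_v(k) is the minimum PD of k leaves inside the pendant subtree below v
(φ_v(0) = 0, φ_leaf(1) = 0; a leaf's pendant edge is charged by its
parent). At an internal vertex the children are folded pairwise in
canonical order by min-plus convolution of (φ_child + ℓ_child·[k>0])
vectors; associativity makes the pairwise fold reproduce the joint
minimisation over all child allocations exactly, for any out-degree, and
keeps the run polynomial without enumerating compositions. No degree
bound is enforced. Backpointers record the winning split at each fold
(ties: the smaller prefix load), so one optimal set is recovered
deterministically and its PD equals the table value exactly. Ultrametric
lengths are not required. Maximum PD loss for t extinctions is the dual:
PD(X) − φ_ρ(n − t), with the extinct set the complement of the recovered
survivor set.

Greedy selection is *not* valid for minimisation: on the 3-leaf tree
(a:3,(b:2,c:2):2) the cheapest single leaf a (PD 3) belongs to no size-2
minPD set ({b,c} scores 6, any pair with a scores ≥ 7). The suite asserts
this divergence.

## Reference trees and the random generator

The bundled trees reconstruct published component structures with integer
edge lengths:

* **T₁** (7 leaves): topology is printed (triple {x1,x2,x3}, fork
  {x4..x7}, cherries {x1,x2}, {x4,x5}, {x6,x7}); the heights (cherries 1,
  root children 4, root 6) are solved from four printed PD constraints
  under ultrametricity. The cherry heights are otherwise unconstrained;
  setting them to 1 matches the constrained one and makes k⁺ = 4 for
  k = 3, consistent with the 20-set count.
* **T₂** (11 leaves, binary): merge heights 1, 1, 2, 2, 3, 3, 3, 4, 4, 5,
  chosen so the branching values {1,2,4,7,9,11} and both printed component
  partitions are reproduced verbatim.
* **T₃** (16 leaves): six deep components completing at height 2 (two
  splitting 1+1, four splitting 1+2 with cherries at height 1), giving the
  size-8 polynomial (x²+2x)²(2x²+3x)⁴. Completing six components to the
  root needs five binary merges; they sit at heights 3, 3, 4, 5, 6 —
  the k = 8 bracket (6, 12) is unaffected by this choice.
* **Mammal structure P** (32 leaves): only the two nested component
  partitions (sizes 1,8,3,2,7,3,5,3 and their 16 refinements) carry
  information, so the fixture uses generic labels and the simplest
  realisation — shallow components as stars at height 1, group merges at
  height 3, root at height 4. Internal topology beyond the partitions and
  the true branch lengths are deliberately not modelled.

`random_ultrametric` draws seeded coalescent-style trees: pairwise merges
at increasing event heights on an exact quarter-unit grid (so heights and
ties are exact binary floats), with a tie probability that reuses the
previous event height (producing simultaneous merges and skipped
branching values) and a multifurcation probability that joins three
lineages at once. It emulates exactly the structural features the theory
must handle — tied heights and polytomies — and nothing about real data
beyond that (no realistic coalescent waiting times, no rate variation),
so passing oracle tests certify combinatorial correctness, not inference
on empirical phylogenies. `brute_force` enumerates all C(n,k) subsets
(capped at 10⁶) and is the independent oracle; optimal sets are collected
within a 1e-9 relative PD band to absorb float summation on
random-length trees, while integer-length fixtures compare exactly.

## Problem sizes in the test suite

Oracle-equivalence checks run on 200 seeded random trees with n in 4..10
and every k (counting, membership, greedy maximisation and the minimum-PD
program against enumeration), plus smaller sweeps for the optimiser and
bounds; perfect-tree closed forms are verified against the generating
function up to α = 4 (n = 16) and against printed values at n = 32. These
sizes exhaust every structural case (ties, skips, polytomies, brackets of
width > 1) while keeping the whole suite around two seconds.

## Known limitations

* Counting requires the ultrametric condition; arbitrary lengths are
  supported only by the PD/greedy/minPD routines.
* maxPD sets are counted, not enumerated; enumeration at scale is
  exponential and out of scope (the brute-force enumerator serves small
  instances only).
* Counting minPD sets in general is open; only the caterpillar special
  case (unique for k ≥ 2) is asserted, by enumeration.
* Newick is the only supported tree format (no NEXUS/NeXML); unrooted
  trees and zero-length edges are rejected by design.
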