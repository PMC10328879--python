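# Methods

## Model

A rooted phylogenetic X-tree is a rooted tree whose leaves carry the taxon
labels X, whose edges point away from the root, and whose internal
vertices all have out-degree ≥ 2; branch lengths are strictly positive
(no ultrametric assumption). The phylogenetic diversity `PD(T, ℓ)` is the
sum of branch lengths.

An **allocation function** distributes PD over the leaves linearly in the
lengths, `φ(x) = Σ_e γ(x, e) ℓ(e)`, with non-negative coefficients; the
conservation requirement `Σ_x φ(x) = PD` is equivalent to every
coefficient column summing to one. A **diversity index** further satisfies
the *descent* condition (an edge's history belongs to its descendants:
`γ(x, e) = 0` if `x` is not below `e`) and the *neutrality* condition (an
edge's coefficient pattern is a function of the shape of its pendant
subtree, constant on symmetry orbits, equal across shape-isomorphic
pendant subtrees). Immediate consequences implemented as validators:
coefficients lie in [0, 1]; each column restricted to the edge's cluster
sums to one; pendant columns are indicator vectors; and each leaf's score
is bracketed by

```
ℓ(e_x)  ≤  φ(x)  ≤  Σ_{e on the root path of x} ℓ(e) / σ_x(e),
```

where `σ_x(e)` is the number of leaves below `e` in positions symmetric to
`x`.

## Canonical shape machinery

Subtree shapes are encoded by AHU-style canonical codes (leaf ↦ `L`,
internal vertex ↦ the sorted tuple of child codes); equal codes ⇔
isomorphic rooted shapes. Children of every vertex are stored in
canonical order (code first, sorted leaf-label set as tie-break), which
makes auto-naming of unlabelled vertices (`v<preorder index>`), Newick
output, ratio positions and corner enumeration reproducible. Two leaves
below a vertex are in the same automorphism orbit iff the sequences of
child-subtree codes along their paths from that vertex agree; this yields
orbits, `σ_x(e)`, and the canonical-position matching used by the
neutrality validator.

Internal non-root vertices are grouped into equivalence classes by the
multiset of their child subtree shapes. A class's degrees of freedom is
the number of *distinct* child shapes minus one. `space_dimension` returns
the classical dimension of the index space: the sum of degrees of freedom
over one representative per class. It is 0 exactly on semi-balanced trees
(every maximal pendant subtree of the root balanced), and at most
`|X| − 2` (see *Known limitations* for the regime where this count is the
exact affine dimension).

## Consistency and flow evaluation

At a vertex `v` with subtrees `T_1 … T_d` and an ancestral edge `e`, the
*group allocation* `Γ_i(v, e)` sums the edge's coefficients over the
leaves of `T_i`. An index is *consistent* when, at every vertex, all
ancestral edges allocate in the same proportions. A consistent index is
determined by one normalised ratio per internal vertex, and its scores
follow from a flow algorithm: walk the edges top-down, pushing each
interior edge's weight onto its child edges in ratio proportions; a
leaf's score is the final weight of its pendant edge. Equivalently, a
coefficient is the product of ratio entries along the path from the
edge's terminal vertex down to the leaf's parent.

Ratio schemes are keyed by class signature, which builds neutrality into
the representation (vertices with identical descendant structure share
ratios; equal child shapes share value). Classes with a single distinct
child shape are forced to the equal split and may be omitted from a
scheme.

Any diversity index coincides, for fixed lengths, with a consistent one:
take at each vertex the length-weighted aggregate ratio
`Σ_e Γ_1(v,e) ℓ(e) : … : Σ_e Γ_d(v,e) ℓ(e)` over its ancestral edges.
Design choices here:

* Members of one class can genuinely receive different aggregate ratios
  (they aggregate differently shaped ancestries with different length
  profiles). `matrix_to_consistent` therefore emits a single class entry
  when all members agree and exact per-vertex overrides otherwise; the
  coincidence of scores is preserved exactly in both cases.
* A vertex that receives no allocation from any ancestral edge has an
  undefined aggregate ratio; the leaf-count-proportional ratio is
  substituted (with a logged notice). Scores are unaffected because no
  weight flows through such a vertex.

## Geometry of the index space

A *corner* index gives, per class, the entire allocation to one distinct
child shape (the `k` positions holding that shape get `1/k` each).
Corners are enumerated lexicographically: classes ordered by
representative preorder index, choices by shape code, so the
all-first-choice corner is always first; materialisation refuses above a
cap (default 4096) while the iterator remains streaming. A
Caratheodory-style basis consists of the all-first-choice corner plus,
per class and per alternative choice, the corner differing only there —
`dimension + 1` elements in total (the unique Fair Proportion point alone
on a semi-balanced tree).

`corner_coordinates` solves for barycentric weights in a corner basis,
exactly over rationals (Gaussian elimination on the normal equations; a
tiny dedicated routine, because the property suites run thousands of
exact solves). By default weights must be convex; the affine
parametrisation relative to the first basis element (in which the first
weight may go negative — already so for the fourth caterpillar corner) is
available via `require_convex=False`.

`sample_index` draws a random consistent index: per free class, the
distinct-shape group totals come from a flat Dirichlet on the simplex,
then are converted to exact rationals (denominators capped at 2^20) and
renormalised so downstream identities hold exactly. Fixed seed ⇒
identical scheme.

## Continuity

An index family (a rule tree ↦ coefficient matrix, e.g. Fair Proportion,
Equal-Splits, or a shape-keyed ratio scheme completed with Fair
Proportion ratios on unseen signatures) is probed for continuity under
edge contraction: the `ℓ(e) → 0` limit of the scores — computed exactly
by zeroing that edge's column contribution, valid by linearity — is
compared with the family's scores on the contracted tree `T/e`. The
package reports both the per-leaf profile and the max-abs defect. Fair
Proportion has zero defect everywhere (its coefficients depend only on
cluster sizes, which contraction preserves); Equal-Splits picks up
positive defects on non-semi-balanced trees (on the unit five-leaf
caterpillar at the edge above the three-leaf subtree, the defect profile
is 1/24, 1/24, 1/12, 1/6, 0 over x1…x5).

## Numerical conventions

All structural quantities and all built-in coefficients are exact
`fractions.Fraction` values; branch lengths are parsed from Newick as
exact rationals (every decimal literal is rational). Equality checks are
exact on rational data; user-supplied float matrices are compared with an
absolute tolerance of 1e-9 (column sums, neutrality equalities,
coincidence). Newick output writes terminating decimals exactly and falls
back to float repr otherwise, so unit- and dyadic-length trees round-trip
exactly. A redundant unary root wrapper (`"(subtree);"` with no label or
length) is collapsed on parse; any other out-degree-1 vertex is rejected.

## Synthetic data

`random_tree(n, seed, multifurcation_prob, length_sampler)` grows a binary
tree by sequential random leaf attachment (each new leaf subdivides a
uniformly chosen edge), then contracts each interior non-root edge
independently with the given probability to create multifurcations;
lengths are 1 unless a sampler is supplied. The generator covers tree
shape and branch-length variation but does not emulate any specific
macroevolutionary prior (no Yule/coalescent waiting times, no
ultrametricity), so passing property suites certify combinatorial and
algebraic correctness, not statistical behaviour on empirical
phylogenies. Property suites run at desk scale: 200–500 trees with up to
12 leaves, 10–50 sampled indices per tree — sizes at which every identity
is checked in exact arithmetic in seconds.

The named fixtures include the five-leaf caterpillar (`cat5`, unit
lengths, two free classes, four corners), five-leaf shapes with one- and
zero-dimensional spaces, a seven-leaf tree with two shape-matched pendant
subtrees exercising the neutrality condition, and a 26-tip hominoid
(great ape + gibbon) tree. The hominoid topology is a *stylised*
transcription: it reproduces the documented symmetry-class structure
(nine one-dof classes, among them a two-member cherry+triple class, a
three-member leaf+cherry class, and two distinct cherry+five-leaf
classes; two zero-dof classes; classical dimension 9) and is not a
species-level phylogenetic claim.

## Known limitations

* **Class-collapsed dimension vs corner geometry.** The classical formula
  implemented by `space_dimension` sums degrees of freedom over one
  representative per class. When every free class has a single member
  (true of all the small worked examples), this equals the affine
  dimension of the corner set and of the full score space. When a free
  class has several members sitting in non-equivalent ancestral contexts,
  the neutrality condition does *not* tie the coefficients of their
  distinct-shaped ancestral edges, and the space of score vectors spans
  more affine directions: on the hominoid fixture the corner set has
  affine rank 13, the per-vertex total `total_degrees_of_freedom`,
  against a classical dimension of 9. The package exposes both counts
  plus `has_singleton_free_classes` to test for the exact regime; the
  test suite asserts the bracketing
  `space_dimension ≤ corner rank ≤ total_degrees_of_freedom ≤ |X| − 2`.
* A fixed Caratheodory basis spans the space affinely, not convexly: some
  indices (e.g. the fourth caterpillar corner) need a different corner
  subset for a convex representation.
* Unrooted trees and phylogenetic networks are out of scope, as are
  abundance-weighted measures and shape statistics unrelated to index
  spaces.
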