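# pdspace

Phylogenetic diversity indices on rooted trees — Fair Proportion,
Equal-Splits, and the convex space containing every diversity index a tree
admits.

## The problem

The phylogenetic diversity of a rooted phylogenetic tree `T` with branch
lengths `ℓ` is the total branch length, `PD(T, ℓ) = Σ_e ℓ(e)`.
Conservation applications (e.g. ranking species by evolutionary
distinctiveness) need that total apportioned among the individual leaf
taxa. A *diversity index* does this through per-edge coefficients
`γ(x, e) ≥ 0` with scores `φ(x) = Σ_e γ(x, e) ℓ(e)`, subject to:

* **conservation** — every column sums to one, so `Σ_x φ(x) = PD(T, ℓ)`;
* **descent** — `γ(x, e) = 0` unless leaf `x` is descended from edge `e`;
* **neutrality** — the coefficients of an edge depend only on the *shape*
  of its pendant subtree, with equal values in symmetric positions.

The two indices in common use are instances:

* **Fair Proportion** (a.k.a. Evolutionary Distinctiveness):
  `γ(x, e) = 1 / |c_T(e)|`, the reciprocal cluster size. It equals the
  Shapley value of the PD coalition game and is the unique index family
  continuous under contraction of short interior edges.
* **Equal-Splits**: `γ(x, e) = 1 / Π(e, x)`, halving (d-thing) the
  allocation at each interior vertex on the way down.

These are just two points in a compact convex set `S(T, ℓ)` of score
vectors. `pdspace` computes the combinatorics and geometry of that set:
symmetry classes of internal vertices and their degrees of freedom, the
space's dimension, its extreme ("corner") indices, barycentric coordinates
of an index in a corner basis, per-leaf score bounds, consistent
(flow-based) evaluation through ratios of allocation, conversion of any
index to a coincident consistent one, and continuity defects under edge
contraction.

## Worked example

The five-leaf caterpillar with unit branch lengths,
`((((x1,x2),x3),x4),x5)`, total PD = 8:

```python
from pdspace import *

t = make_fixture("cat5")
fp = evaluate(fp_matrix(t), t)
es = evaluate(es_matrix(t), t)
for x in t.leaves:
    print(x, fp[x], es[x])
```

```
x1 25/12 15/8
x2 25/12 15/8
x3 19/12 7/4
x4 5/4 3/2
x5 1 1
```

Each column sums to 8 = PD: the cherry leaves x1, x2 embody the most
evolutionary history, the isolated leaf x5 exactly its own pendant edge.
The index space here is two-dimensional; its four corner indices are
obtained by pushing each free vertex's allocation entirely one way:

```python
for c in list_corners(t):
    print(c.choice_indices, [str(v) for _, v in c.scores])
```

```
(0, 0, 0) ['5/2', '5/2', '1', '1', '1']
(0, 1, 0) ['3/2', '3/2', '3', '1', '1']
(1, 0, 0) ['2', '2', '1', '2', '1']
(1, 1, 0) ['3/2', '3/2', '2', '2', '1']
```

In the basis of the first three corners (κ, λ, μ), Fair Proportion sits at
`(p, q) = (7/24, 1/4)` and Equal-Splits at `(9/24, 1/2)`:

```python
basis = list_corners(t)[:3]
print(corner_coordinates(fp, basis)[1:])   # (Fraction(7, 24), Fraction(1, 4))
print(corner_coordinates(es, basis)[1:])   # (Fraction(9, 24), Fraction(1, 2))
```

The same functionality is exposed on the command line:

```bash
pdspace score --tree cat5.nwk --index fp
pdspace dimension --tree cat5.nwk
pdspace corners --tree cat5.nwk
pdspace continuity --tree cat5.nwk --index es
```

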