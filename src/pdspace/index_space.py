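"""Geometry of the convex space S(T, l) of diversity-index score vectors.

The space of all diversity indices on a rooted tree, viewed through their
score vectors, is a compact convex set whose dimension equals the total
degrees of freedom of the tree's ``~``-equivalence classes.  Its extreme
points ("corner" indices) arise by giving each class's entire allocation to
one of its distinct child shapes; every index is a convex combination of at
most ``dimension + 1`` corners (Caratheodory), and the combination weights
give barycentric coordinates of an index relative to a corner basis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from ._exact import DEFAULT_TOL, Number, all_exact, exact_lstsq, near
from .consistency import RatioScheme, _ancestral_edges, group_allocation, flow_scores
from .indices import CoefficientMatrix, IndexScoreVector
from .shape import ClassKey, IndexSpaceSummary, equivalence_classes, sigma_count
from .tree import EdgeRef, RootedTree

#: refuse to materialise more corners than this without explicit consent
DEFAULT_CORNER_CAP = 4096


class NotInSpanError(ValueError):
    """Score vector does not lie in the affine span of the basis corners."""


class OutsideHullError(ValueError):
    """Score vector lies in the span but outside the convex hull."""


@dataclass(frozen=True)
class CornerIndex:
    """An extreme point of S(T, l).

    ``choices`` maps each equivalence-class key to the distinct child shape
    (by index into the class's sorted ``child_shapes``) that receives the
    entire allocation; positions of that shape share it equally, all other
    positions get zero.
    """

    choices: Tuple[Tuple[ClassKey, int], ...]
    scheme: RatioScheme
    scores: IndexScoreVector

    @property
    def choice_indices(self) -> Tuple[int, ...]:
        return tuple(i for _, i in self.choices)


def _extreme_ratio(key: ClassKey, shape_idx: int) -> Tuple[Fraction, ...]:
    """All allocation to the ``shape_idx``-th distinct child shape: the
    ``k`` positions holding that shape get ``1/k`` each, others zero."""
    distinct = sorted(set(key))
    chosen = distinct[shape_idx]
    k = key.count(chosen)
    return tuple(Fraction(1, k) if code == chosen else Fraction(0) for code in key)


def corner_scheme(
    tree: RootedTree,
    choice: Dict[ClassKey, int],
    summary: Optional[IndexSpaceSummary] = None,
) -> RatioScheme:
    """Ratio scheme of the corner selecting, per class, one child shape."""
    if summary is None:
        summary = equivalence_classes(tree)
    ratios = {}
    for cls in summary.classes:
        idx = choice.get(cls.key, 0)
        ratios[cls.key] = _extreme_ratio(cls.key, idx)
    return RatioScheme(ratios)


def corner_indices(
    tree: RootedTree,
    lengths: Optional[Dict[EdgeRef, Number]] = None,
) -> Iterator[CornerIndex]:
    """Iterate all corner (extreme) indices of S(T, l).

    One corner per element of the product, over ``~``-equivalence classes
    (ordered by representative preorder index), of the distinct child
    shapes at that class (sorted by shape code); lexicographic order, so
    the all-first-choice corner comes first.
    """
    summary = equivalence_classes(tree)
    keys = [cls.key for cls in summary.classes]
    option_counts = [len(cls.child_shapes) for cls in summary.classes]
    for combo in itertools.product(*(range(c) for c in option_counts)):
        choice = dict(zip(keys, combo))
        scheme = corner_scheme(tree, choice, summary)
        scores = flow_scores(tree, scheme, lengths)
        yield CornerIndex(tuple(zip(keys, combo)), scheme, scores)


def corner_count(tree: RootedTree) -> int:
    return equivalence_classes(tree).corner_count


def list_corners(
    tree: RootedTree,
    lengths: Optional[Dict[EdgeRef, Number]] = None,
    cap: int = DEFAULT_CORNER_CAP,
) -> List[CornerIndex]:
    """Materialise all corners; refuses above ``cap`` (the iterator
    :func:`corner_indices` still works for streaming use)."""
    count = corner_count(tree)
    if count > cap:
        raise ValueError(
            f"tree has {count} corner indices (> cap {cap}); iterate "
            "corner_indices() or raise the cap explicitly"
        )
    return list(corner_indices(tree, lengths))


def caratheodory_basis(
    tree: RootedTree,
    lengths: Optional[Dict[EdgeRef, Number]] = None,
) -> List[CornerIndex]:
    """A Caratheodory basis of ``dimension + 1`` corner indices.

    ``B1`` is the all-first-choice corner; each further element differs
    from ``B1`` in exactly one class, switched to one alternative child
    shape — one element per degree of freedom.  A semi-balanced tree has a
    single corner (the Fair Proportion point), returned alone.
    """
    summary = equivalence_classes(tree)
    keys = [cls.key for cls in summary.classes]
    base_choice = {key: 0 for key in keys}
    basis = [
        CornerIndex(
            tuple((key, 0) for key in keys),
            corner_scheme(tree, base_choice, summary),
            flow_scores(tree, corner_scheme(tree, base_choice, summary), lengths),
        )
    ]
    for cls in summary.classes:
        for alt in range(1, len(cls.child_shapes)):
            choice = dict(base_choice)
            choice[cls.key] = alt
            scheme = corner_scheme(tree, choice, summary)
            basis.append(
                CornerIndex(
                    tuple((key, choice[key]) for key in keys),
                    scheme,
                    flow_scores(tree, scheme, lengths),
                )
            )
    return basis


def corner_coordinates(
    scores: IndexScoreVector | Sequence[Number],
    basis: Sequence[CornerIndex],
    tol: float = DEFAULT_TOL,
    require_convex: bool = True,
) -> Tuple[Number, ...]:
    """Barycentric weights expressing ``scores`` in the given corner basis.

    Solves ``sum_i w_i * basis_i = scores`` with ``sum_i w_i = 1`` exactly
    over rationals (least squares over the normal equations); the weights
    beyond the first are the ``(p, q, ...)`` parametrisation relative to
    ``B1``.  Raises :class:`NotInSpanError` if no exact/near solution
    exists and, when ``require_convex`` (the default),
    :class:`OutsideHullError` if a weight is negative.  With
    ``require_convex=False`` the affine parametrisation is returned even
    outside the simplex of the basis (the weight on ``B1`` may then be
    negative, as for the fourth corner of the five-leaf caterpillar).
    """
    target = list(scores.values) if isinstance(scores, IndexScoreVector) else list(scores)
    cols = [list(b.scores.values) for b in basis]
    if any(len(c) != len(target) for c in cols):
        raise ValueError("basis and score vector have mismatched leaf counts")
    exact = all_exact(target) and all(all_exact(c) for c in cols)
    nrows = len(target) + 1
    if exact:
        a = [
            [Fraction(cols[j][i]) for j in range(len(cols))]
            for i in range(len(target))
        ]
        a.append([Fraction(1)] * len(cols))
        b = [Fraction(t) for t in target] + [Fraction(1)]
        weights, residual_zero = exact_lstsq(a, b)
        if not residual_zero:
            raise NotInSpanError("score vector is not in the span of the basis")
        if require_convex and any(w < 0 for w in weights):
            raise OutsideHullError(
                "score vector lies outside the convex hull of the basis"
            )
        return tuple(weights)
    a = np.array(
        [[float(c[i]) for c in cols] for i in range(len(target))] + [[1.0] * len(cols)]
    )
    b = np.array([float(t) for t in target] + [1.0])
    w, *_ = np.linalg.lstsq(a, b, rcond=None)
    if np.max(np.abs(a @ w - b)) > tol:
        raise NotInSpanError("score vector is not in the span of the basis")
    if require_convex and np.min(w) < -tol:
        raise OutsideHullError("score vector lies outside the convex hull of the basis")
    return tuple(float(x) for x in w)


def score_bounds(tree: RootedTree, x: str) -> Tuple[Number, Number]:
    """Attainable range of phi(x) over all diversity indices:
    pendant length below, orbit-weighted path sum above."""
    path = tree.root_path(x)
    lower = tree.length(path[-1])
    upper = sum(
        (Fraction(tree.length(e)) / sigma_count(tree, x, e) for e in path),
        Fraction(0),
    )
    return lower, upper


def sample_index(tree: RootedTree, seed: int) -> RatioScheme:
    """Draw a random consistent diversity index, reproducibly.

    Per equivalence class, distinct-child-shape group totals are drawn from
    a flat Dirichlet on the simplex (the neutrality condition then forces
    equal shares within a group), converted to exact rationals
    (denominators capped at 2**20) and renormalised so every downstream
    identity holds exactly.  A semi-balanced tree has no free class and the
    unique index (Fair Proportion's point) is returned for any seed.
    """
    rng = np.random.default_rng(seed)
    summary = equivalence_classes(tree)
    ratios: Dict[ClassKey, Tuple[Fraction, ...]] = {}
    for cls in summary.classes:
        distinct = list(cls.child_shapes)
        if len(distinct) == 1:
            d = len(cls.key)
            ratios[cls.key] = tuple(Fraction(1, d) for _ in range(d))
            continue
        draw = rng.dirichlet(np.ones(len(distinct)))
        totals = [Fraction(float(t)).limit_denominator(2**20) for t in draw]
        norm = sum(totals, Fraction(0))
        if norm == 0:  # pragma: no cover - dirichlet never returns all zeros
            totals = [Fraction(1, len(distinct))] * len(distinct)
            norm = Fraction(1)
        totals = [t / norm for t in totals]
        per_shape = {
            shape: totals[i] / cls.key.count(shape)
            for i, shape in enumerate(distinct)
        }
        ratios[cls.key] = tuple(per_shape[code] for code in cls.key)
    return RatioScheme(ratios)


def check_family_properties(
    family: Callable[[RootedTree], CoefficientMatrix],
    trees: Iterable[RootedTree],
    tol: float = DEFAULT_TOL,
) -> Tuple[bool, bool]:
    """Check two cross-tree regularity properties of an index family.

    * Property 1 — the normalised ratio of allocations at a vertex depends
      only on the leaf counts of its maximal pendant subtrees, not their
      shapes (checked across every vertex/ancestral edge of every tree).
    * Property 2 — a subtree with at least as many leaves never receives a
      smaller allocation.

    Both hold for Fair Proportion and Equal-Splits.
    """
    property1 = True
    property2 = True
    seen: Dict[Tuple[int, ...], Tuple[Tuple[int, Number], ...]] = {}
    for tree in trees:
        matrix = family(tree)
        for v in tree.vertices:
            if tree.is_leaf(v) or v == tree.root:
                continue
            counts = [tree.leaf_count(c) for c in tree.children(v)]
            for e in _ancestral_edges(tree, v):
                gam = group_allocation(matrix, tree, v, e)
                total = sum(gam, Fraction(0))
                for i in range(len(gam)):
                    for j in range(len(gam)):
                        if counts[i] >= counts[j] and gam[i] < gam[j] and not near(
                            gam[i], gam[j], tol
                        ):
                            property2 = False
                if total == 0:
                    continue
                normed = tuple(g / total for g in gam)
                profile = tuple(sorted(counts))
                canon = tuple(sorted(zip(counts, normed)))
                # equal counts within a vertex must carry equal values
                by_count: Dict[int, Number] = {}
                for c, val in zip(counts, normed):
                    if c in by_count and not near(by_count[c], val, tol):
                        property1 = False
                    by_count.setdefault(c, val)
                if profile in seen:
                    ref = seen[profile]
                    if len(ref) != len(canon) or any(
                        rc != cc or not near(rv, cv, tol)
                        for (rc, rv), (cc, cv) in zip(ref, canon)
                    ):
                        property1 = False
                else:
                    seen[profile] = canon
    return property1, property2
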