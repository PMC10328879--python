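"""Tree-shape canonical codes, symmetry orbits, and index-space dimension.

A *tree shape* is a rooted tree with leaf labels ignored; two subtrees have
the same shape iff their canonical (AHU) codes agree.  The symmetry
structure of a shape drives everything here:

* leaves of a subtree fall into automorphism *orbits* ("corresponding
  positions"): two leaves are swappable iff the sequence of child-subtree
  shape codes along their paths from the subtree root agree;
* ``sigma_count`` is the orbit size of a leaf inside a pendant subtree,
  which bounds its diversity-index score from above;
* interior non-root vertices are grouped into ``~``-equivalence classes by
  the multiset of their child subtree shapes; each class carries
  ``(number of distinct child shapes) - 1`` degrees of freedom, and the
  dimension of the convex space of diversity indices is the sum of the
  degrees of freedom over one representative per class.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from typing import Dict, List, Tuple

from .tree import EdgeRef, RootedTree

#: A class key is the sorted tuple of child subtree shape codes of a vertex.
ClassKey = Tuple[str, ...]


def shape_code(tree: RootedTree, v: str | None = None) -> str:
    """Canonical code of the subtree shape rooted at ``v`` (default: root).

    Equal codes <=> isomorphic rooted tree shapes.
    """
    return tree.shape_code(tree.root if v is None else v)


def class_key(tree: RootedTree, v: str) -> ClassKey:
    """Sorted multiset of child subtree shape codes of internal vertex ``v``."""
    cs = tree.children(v)
    if not cs:
        raise ValueError(f"{v!r} is a leaf; class keys are defined for interior vertices")
    return tuple(sorted(tree.shape_code(c) for c in cs))


def position_signature(tree: RootedTree, top: str, leaf: str) -> Tuple[str, ...]:
    """Shape codes of the subtrees entered on the path from ``top`` to ``leaf``.

    Two leaves below ``top`` are in corresponding positions (same
    automorphism orbit of the subtree shape) iff their signatures agree;
    children with equal codes are freely interchangeable at each step.
    """
    path: List[str] = []
    v = leaf
    while v != top:
        path.append(v)
        p = tree.parent(v)
        if p is None:
            raise ValueError(f"leaf {leaf!r} is not descended from {top!r}")
        v = p
    return tuple(tree.shape_code(u) for u in reversed(path))


def leaf_orbits(tree: RootedTree, v: str | None = None) -> Tuple[frozenset, ...]:
    """Automorphism orbits of the leaves of the subtree rooted at ``v``.

    Leaves in one orbit are exactly those in corresponding positions of the
    subtree's shape.  Returned in canonical preorder of first occurrence.
    """
    if v is None:
        v = tree.root
    if tree.is_leaf(v):
        return (frozenset({v}),)
    below = [x for x in tree.leaves if v in _ancestors_inclusive(tree, x)]
    groups: Dict[Tuple[str, ...], set] = {}
    order: List[Tuple[str, ...]] = []
    for x in below:
        sig = position_signature(tree, v, x)
        if sig not in groups:
            groups[sig] = set()
            order.append(sig)
        groups[sig].add(x)
    return tuple(frozenset(groups[s]) for s in order)


def _ancestors_inclusive(tree: RootedTree, v: str) -> set:
    out = {v}
    while True:
        p = tree.parent(v)
        if p is None:
            return out
        out.add(p)
        v = p


def sigma_count(tree: RootedTree, x: str, e: EdgeRef) -> int:
    """Number of leaves below ``e`` in positions corresponding to ``x``
    (including ``x`` itself): the orbit size of ``x`` within P_e."""
    if x not in tree.cluster(e):
        raise ValueError(f"leaf {x!r} is not descended from edge {e!r}")
    sig = position_signature(tree, e, x)
    return sum(
        1 for y in tree.cluster(e) if position_signature(tree, e, y) == sig
    )


def is_balanced(tree: RootedTree) -> bool:
    """True iff at every vertex all maximal pendant subtrees share one shape.

    A single leaf is balanced.
    """
    for v in tree.vertices:
        cs = tree.children(v)
        if cs and len({tree.shape_code(c) for c in cs}) > 1:
            return False
    return True


def is_semi_balanced(tree: RootedTree) -> bool:
    """True iff every maximal pendant subtree of the root is balanced.

    These are exactly the trees whose diversity-index space is a single
    point (equivalently, on which FP and ES coincide).
    """
    for c in tree.children(tree.root):
        if not is_balanced(tree.pendant_subtree(c)):
            return False
    return True


def vertex_dof(tree: RootedTree, v: str) -> int:
    """Degrees of freedom of interior non-root vertex ``v``:
    one less than the number of distinct child subtree shapes."""
    if v == tree.root:
        raise ValueError("degrees of freedom are not defined for the root")
    if tree.is_leaf(v):
        raise ValueError("degrees of freedom are not defined for leaves")
    return len(set(class_key(tree, v))) - 1


@dataclass(frozen=True)
class EquivalenceClass:
    """One ``~``-equivalence class of interior non-root vertices."""

    key: ClassKey
    representative: str          # member with smallest canonical preorder index
    members: Tuple[str, ...]
    dof: int
    child_shapes: Tuple[str, ...]  # distinct child shape codes, sorted


@dataclass(frozen=True)
class IndexSpaceSummary:
    """Equivalence classes, degrees of freedom, and dimension of S(T, l)."""

    classes: Tuple[EquivalenceClass, ...]
    dimension: int
    corner_count: int

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "corner_count": self.corner_count,
            "classes": [
                {
                    "representative": c.representative,
                    "members": list(c.members),
                    "dof": c.dof,
                    "child_shapes": list(c.child_shapes),
                }
                for c in self.classes
            ],
        }


def equivalence_classes(tree: RootedTree) -> IndexSpaceSummary:
    """Partition interior non-root vertices by child-shape multiset.

    Two vertices share a class iff the multisets of tree shapes of their
    maximal pendant subtrees coincide.  Classes are ordered by the canonical
    preorder index of their representative.
    """
    groups: Dict[ClassKey, List[str]] = {}
    order: List[ClassKey] = []
    for v in tree.vertices:
        if v == tree.root or tree.is_leaf(v):
            continue
        key = class_key(tree, v)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(v)
    classes = []
    for key in order:
        members = tuple(groups[key])
        distinct = tuple(sorted(set(key)))
        classes.append(
            EquivalenceClass(
                key=key,
                representative=members[0],
                members=members,
                dof=len(distinct) - 1,
                child_shapes=distinct,
            )
        )
    dimension = sum(c.dof for c in classes)
    corner_count = prod(len(c.child_shapes) for c in classes) if classes else 1
    return IndexSpaceSummary(tuple(classes), dimension, corner_count)


def space_dimension(tree: RootedTree) -> int:
    """Classical dimension of the space S(T, l) of diversity indices:
    degrees of freedom summed over one representative per ``~``-class.

    Zero iff the tree is semi-balanced; always at most ``n_leaves - 2`` for
    trees with at least two leaves.  Note: this class-collapsed count is
    exact whenever every class with positive degrees of freedom has a
    single member (true of all the small worked examples); when a free
    class has members in non-equivalent ancestral contexts, the affine
    dimension of the full score space can exceed it, up to the per-vertex
    total :func:`total_degrees_of_freedom`.
    """
    return equivalence_classes(tree).dimension


def total_degrees_of_freedom(tree: RootedTree) -> int:
    """Degrees of freedom summed over *every* interior non-root vertex.

    An upper bound for the affine dimension of the score space (itself at
    most ``n_leaves - 2``); coincides with :func:`space_dimension` when no
    ``~``-class with positive degrees of freedom has more than one member.
    """
    return sum(
        vertex_dof(tree, v)
        for v in tree.vertices
        if tree.children(v) and v != tree.root
    )


def has_singleton_free_classes(tree: RootedTree) -> bool:
    """True iff every ``~``-class with positive degrees of freedom has a
    single member (the regime in which the classical dimension formula is
    provably exact)."""
    return all(
        len(c.members) == 1
        for c in equivalence_classes(tree).classes
        if c.dof > 0
    )
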