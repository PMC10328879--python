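"""Consistent diversity indices: ratio schemes, flow evaluation, and the
conversion of an arbitrary index into a coincident consistent one.

A diversity index is *consistent* at a vertex ``v`` when every edge
ancestral to ``v`` splits its allocation among the maximal pendant subtrees
below ``v`` in the same proportions.  A consistent index is therefore fully
described by one normalised *ratio of allocations* per internal vertex, and
its scores can be computed by a flow algorithm that pushes each interior
edge's weight down onto its child edges until only pendant weights remain.

Ratios are keyed by the vertex's ``~``-equivalence-class signature (the
sorted multiset of child subtree shape codes), which builds the neutrality
condition into the representation: vertices with the same descendant
structure necessarily share ratios, and positions with equal child shapes
carry equal values.  Per-vertex overrides are supported for the one
construction that needs them (see :func:`matrix_to_consistent`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Mapping, Optional, Tuple

from ._exact import DEFAULT_TOL, Number, format_number, near, parse_number
from .indices import CoefficientMatrix, IndexScoreVector, evaluate
from .shape import ClassKey, class_key
from .tree import EdgeRef, RootedTree

logger = logging.getLogger("pdspace")


class SchemeError(ValueError):
    """Ratio scheme violates its contract (coverage or invariants)."""


@dataclass(frozen=True)
class RatioScheme:
    """Normalised ratios of allocation, keyed by vertex class signature.

    ``class_ratios[key]`` lists one non-negative share per canonical child
    position (children sorted by shape code), summing to one, with equal
    values at positions whose child shapes coincide.  ``vertex_ratios``
    optionally overrides specific vertices by name.  Classes whose children
    all share one shape may be omitted: their ratio is forced to the equal
    split ``(1/d, ..., 1/d)``.
    """

    class_ratios: Mapping[ClassKey, Tuple[Number, ...]] = field(default_factory=dict)
    vertex_ratios: Mapping[str, Tuple[Number, ...]] = field(default_factory=dict)

    def ratios_for(self, tree: RootedTree, v: str) -> Tuple[Number, ...]:
        """Ratio tuple for internal vertex ``v``, in canonical child order."""
        if v in self.vertex_ratios:
            return tuple(self.vertex_ratios[v])
        key = class_key(tree, v)
        if key in self.class_ratios:
            return tuple(self.class_ratios[key])
        if len(set(key)) == 1:
            d = len(key)
            return tuple(Fraction(1, d) for _ in range(d))
        raise SchemeError(f"scheme has no ratio for class {key!r} (vertex {v!r})")

    def validate(self, tree: RootedTree, tol: float = DEFAULT_TOL) -> None:
        """Check coverage and invariants against ``tree``; raise SchemeError."""
        for v in tree.vertices:
            cs = tree.children(v)
            if not cs or v == tree.root:
                continue
            ratios = self.ratios_for(tree, v)
            if len(ratios) != len(cs):
                raise SchemeError(
                    f"ratio for vertex {v!r} has {len(ratios)} entries, "
                    f"expected {len(cs)}"
                )
            if any(r < 0 for r in ratios):
                raise SchemeError(f"negative ratio entry at vertex {v!r}")
            if not near(sum(ratios, Fraction(0)), Fraction(1), tol):
                raise SchemeError(f"ratio at vertex {v!r} is not normalised")
            codes = [tree.shape_code(c) for c in cs]
            for i in range(len(cs)):
                for j in range(i + 1, len(cs)):
                    if codes[i] == codes[j] and not near(ratios[i], ratios[j], tol):
                        raise SchemeError(
                            f"equal child shapes at vertex {v!r} carry "
                            "unequal ratio values"
                        )

    # -- JSON --------------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "classes": [
                {"signature": list(key), "ratios": [format_number(r) for r in rs]}
                for key, rs in self.class_ratios.items()
            ],
        }
        if self.vertex_ratios:
            payload["vertices"] = [
                {"vertex": v, "ratios": [format_number(r) for r in rs]}
                for v, rs in self.vertex_ratios.items()
            ]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RatioScheme":
        payload = json.loads(text)
        class_ratios = {
            tuple(entry["signature"]): tuple(parse_number(r) for r in entry["ratios"])
            for entry in payload.get("classes", [])
        }
        vertex_ratios = {
            entry["vertex"]: tuple(parse_number(r) for r in entry["ratios"])
            for entry in payload.get("vertices", [])
        }
        return cls(class_ratios, vertex_ratios)


def fp_ratios(key: ClassKey) -> Tuple[Fraction, ...]:
    """The Fair Proportion ratio for a class: shares proportional to the
    leaf counts of the child shapes."""
    counts = [code.count("L") for code in key]
    total = sum(counts)
    return tuple(Fraction(c, total) for c in counts)


def fp_scheme(tree: RootedTree) -> RatioScheme:
    """Class-keyed ratio scheme reproducing Fair Proportion on ``tree``."""
    ratios = {}
    for v in tree.vertices:
        if v == tree.root or tree.is_leaf(v):
            continue
        key = class_key(tree, v)
        ratios.setdefault(key, fp_ratios(key))
    return RatioScheme(ratios)


# ---------------------------------------------------------------------------
# Group allocations and the consistency predicate
# ---------------------------------------------------------------------------


def group_allocation(
    matrix: CoefficientMatrix, tree: RootedTree, v: str, e: EdgeRef
) -> Tuple[Number, ...]:
    """Gamma_i(v, e): total coefficient of edge ``e`` over the leaves of the
    i-th maximal pendant subtree below ``v``, in canonical child order."""
    cs = tree.children(v)
    if not cs:
        raise ValueError(f"{v!r} is a leaf; group allocations need an interior vertex")
    if v != e and v not in _descendants_of_edge(tree, e):
        raise ValueError(f"vertex {v!r} is not descended from edge {e!r}")
    return tuple(
        sum((matrix.get(x, e) for x in sorted(tree.cluster(c))), Fraction(0))
        for c in cs
    )


def _descendants_of_edge(tree: RootedTree, e: EdgeRef) -> set:
    out = set()
    stack = [e]
    while stack:
        v = stack.pop()
        out.add(v)
        stack.extend(tree.children(v))
    return out


def _ancestral_edges(tree: RootedTree, v: str) -> Tuple[EdgeRef, ...]:
    """Edges ``v`` is descended from, nearest first (the parent edge first)."""
    out = []
    u = v
    while u != tree.root:
        out.append(u)
        u = tree.parent(u)
    return tuple(out)


def is_consistent(
    matrix: CoefficientMatrix, tree: RootedTree, tol: float = DEFAULT_TOL
) -> bool:
    """True iff at every internal vertex the ratio of allocations is the
    same (up to non-negative scaling) for every ancestral edge."""
    for v in tree.vertices:
        if tree.is_leaf(v) or v == tree.root:
            continue
        ancestral = _ancestral_edges(tree, v)
        base = group_allocation(matrix, tree, v, ancestral[0])
        base_total = sum(base, Fraction(0))
        for e in ancestral[1:]:
            gam = group_allocation(matrix, tree, v, e)
            total = sum(gam, Fraction(0))
            if base_total == 0:
                if total != 0:
                    return False
                continue
            # proportional: gam == (total / base_total) * base
            for g, b in zip(gam, base):
                if not near(g * base_total, b * total, tol):
                    return False
    return True


# ---------------------------------------------------------------------------
# Ratios -> coefficients, and flow evaluation
# ---------------------------------------------------------------------------


def ratios_to_matrix(tree: RootedTree, scheme: RatioScheme) -> CoefficientMatrix:
    """Reconstruct coefficients from ratios of allocation.

    ``gamma(x, e)`` is the product of the ratio entries at the vertices on
    the path from ``e``'s terminal vertex down to the parent of ``x``
    (an empty product, i.e. 1, for the pendant edge of ``x``).
    """
    scheme.validate(tree)
    # per-vertex ratio lookup aligned with canonical child order
    vertex_ratio: Dict[str, Tuple[Number, ...]] = {
        v: scheme.ratios_for(tree, v)
        for v in tree.vertices
        if tree.children(v) and v != tree.root
    }
    rows = []
    for x in tree.leaves:
        path = tree.root_path(x)
        row = {e: Fraction(0) for e in tree.edges}
        # products accumulate upwards from the parent of x
        acc = Fraction(1)
        row[path[-1]] = acc  # pendant edge: empty product
        for idx in range(len(path) - 2, -1, -1):
            v = path[idx]  # terminal vertex of this interior edge
            child_on_path = path[idx + 1]
            pos = tree.children(v).index(child_on_path)
            acc = vertex_ratio[v][pos] * acc
            row[v] = acc
        rows.append(tuple(row[e] for e in tree.edges))
    return CoefficientMatrix(tree.leaves, tree.edges, tuple(rows))


def flow_scores(
    tree: RootedTree,
    scheme: RatioScheme,
    lengths: Optional[Mapping[EdgeRef, Number]] = None,
) -> IndexScoreVector:
    """Scores of the consistent index given by ``scheme``, via edge flow.

    Each interior edge's weight is pushed onto its immediate descendant
    edges in ratio proportions (top-down) until only pendant edges carry
    weight; a leaf's score is the final weight of its pendant edge.
    Coincides exactly with ``evaluate(ratios_to_matrix(tree, scheme))``.
    """
    scheme.validate(tree)
    if not tree.edges:
        return IndexScoreVector(tree.leaves, (Fraction(0),) * tree.n_leaves)
    weights: Dict[EdgeRef, Number] = {
        e: (lengths[e] if lengths is not None else tree.length(e))
        for e in tree.edges
    }
    for e in tree.edges:  # canonical preorder = top-down
        cs = tree.children(e)
        if not cs:
            continue
        ratios = scheme.ratios_for(tree, e)
        w = weights[e]
        for c, r in zip(cs, ratios):
            weights[c] = weights[c] + r * w
        weights[e] = Fraction(0)
    return IndexScoreVector(tree.leaves, tuple(weights[x] for x in tree.leaves))


# ---------------------------------------------------------------------------
# Any index -> coincident consistent index
# ---------------------------------------------------------------------------


def matrix_to_consistent(
    matrix: CoefficientMatrix,
    tree: RootedTree,
    lengths: Optional[Mapping[EdgeRef, Number]] = None,
    tol: float = DEFAULT_TOL,
) -> RatioScheme:
    """Consistent ratio scheme whose flow scores coincide with ``matrix``
    on this tree and length assignment.

    At each internal non-root vertex the ratio of allocations is the
    length-weighted aggregate over all ancestral edges::

        sum_e Gamma_1(v,e) l(e) : ... : sum_e Gamma_d(v,e) l(e)

    normalised to sum to one.  When every member of a ``~``-equivalence
    class receives the same ratio the scheme stores a single class entry;
    otherwise per-vertex overrides preserve the exact coincidence.  A vertex
    through which the index allocates nothing (all-zero aggregate) has an
    undefined ratio; the leaf-count-proportional (Fair Proportion) ratio is
    substituted with a logged notice — scores are unaffected since no
    weight flows through such a vertex.
    """
    get_len = (lambda e: lengths[e]) if lengths is not None else tree.length
    per_vertex: Dict[str, Tuple[Number, ...]] = {}
    for v in tree.vertices:
        if tree.is_leaf(v) or v == tree.root:
            continue
        sums = [Fraction(0)] * len(tree.children(v))
        for e in _ancestral_edges(tree, v):
            gam = group_allocation(matrix, tree, v, e)
            for i, g in enumerate(gam):
                sums[i] = sums[i] + g * get_len(e)
        total = sum(sums, Fraction(0))
        if total == 0:
            key = class_key(tree, v)
            per_vertex[v] = fp_ratios(key)
            logger.warning(
                "vertex %r receives no allocation from any ancestral edge; "
                "substituting the leaf-count-proportional ratio", v,
            )
        else:
            per_vertex[v] = tuple(s / total for s in sums)

    # collapse to class entries where all members agree
    class_entries: Dict[ClassKey, Tuple[Number, ...]] = {}
    overrides: Dict[str, Tuple[Number, ...]] = {}
    conflicted: set = set()
    for v, ratios in per_vertex.items():
        key = class_key(tree, v)
        if key in conflicted:
            continue
        if key not in class_entries:
            class_entries[key] = ratios
        elif not all(near(a, b, tol) for a, b in zip(class_entries[key], ratios)):
            conflicted.add(key)
    for v, ratios in per_vertex.items():
        if class_key(tree, v) in conflicted:
            overrides[v] = ratios
    for key in conflicted:
        del class_entries[key]
    return RatioScheme(class_entries, overrides)
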