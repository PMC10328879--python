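"""Coefficient-matrix representation of allocation functions and diversity
indices, with the built-in Fair Proportion, Equal-Splits and uniform rules.

An allocation function distributes the total phylogenetic diversity
PD(T, l) = sum of edge lengths over the leaves, linearly in the lengths:
``score(x) = sum_e gamma(x, e) * l(e)`` with ``gamma >= 0`` and every column
of the coefficient matrix summing to one.  A *diversity index* additionally
satisfies

* the descent condition: ``gamma(x, e) = 0`` unless ``x`` is descended
  from ``e`` (history arising on an edge belongs to its descendants), and
* the neutrality condition: the coefficients of an edge depend only on the
  tree shape of its pendant subtree, equal values in corresponding
  positions.

Fair Proportion uses ``gamma(x, e) = 1/|c_T(e)|``; Equal-Splits halves (or
d-ths) the allocation at every interior vertex on the way down, giving
``gamma(x, e) = 1/Pi(e, x)`` with ``Pi`` the product of out-degrees on the
path from the terminal vertex of ``e`` to ``x``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from ._exact import DEFAULT_TOL, Number, all_exact, format_number, near, parse_number
from .shape import position_signature
from .tree import EdgeRef, RootedTree


class MatrixShapeError(ValueError):
    """Coefficient matrix does not match the tree's leaves/edges."""


@dataclass(frozen=True)
class CoefficientMatrix:
    """An ``n x m`` matrix of coefficients gamma(leaf, edge).

    ``leaf_order`` and ``edge_order`` are the canonical leaf/edge orders of
    the tree it was built for; ``rows[i][j]`` is gamma(leaf i, edge j).
    Entries are exact rationals by default; floats are accepted from user
    input and compared with a 1e-9 absolute tolerance.
    """

    leaf_order: Tuple[str, ...]
    edge_order: Tuple[EdgeRef, ...]
    rows: Tuple[Tuple[Number, ...], ...]

    def __post_init__(self):
        if len(self.rows) != len(self.leaf_order) or any(
            len(r) != len(self.edge_order) for r in self.rows
        ):
            raise MatrixShapeError("matrix dimensions do not match orders")

    def get(self, leaf: str, edge: EdgeRef) -> Number:
        try:
            i = self.leaf_order.index(leaf)
            j = self.edge_order.index(edge)
        except ValueError as exc:
            raise LookupError(str(exc)) from exc
        return self.rows[i][j]

    @property
    def is_exact(self) -> bool:
        return all(all_exact(r) for r in self.rows)

    def column(self, edge: EdgeRef) -> Tuple[Number, ...]:
        j = self.edge_order.index(edge)
        return tuple(r[j] for r in self.rows)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self) -> str:
        out = io.StringIO()
        out.write("leaf\t" + "\t".join(self.edge_order) + "\n")
        for leaf, row in zip(self.leaf_order, self.rows):
            out.write(leaf + "\t" + "\t".join(format_number(v) for v in row) + "\n")
        return out.getvalue()

    @classmethod
    def from_tsv(cls, text: str, tree: RootedTree) -> "CoefficientMatrix":
        """Load a matrix from TSV and normalise to the tree's canonical
        leaf/edge order.  Entries may be ``p/q`` or decimal."""
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if header[0] != "leaf":
            raise ValueError("first header cell must be 'leaf'")
        edges = header[1:]
        data: Dict[str, Dict[str, Fraction]] = {}
        for ln in lines[1:]:
            cells = ln.split("\t")
            data[cells[0]] = {
                e: parse_number(c) for e, c in zip(edges, cells[1:])
            }
        if set(data) != set(tree.leaves):
            raise MatrixShapeError("TSV leaves do not match the tree")
        if set(edges) != set(tree.edges):
            raise MatrixShapeError("TSV edges do not match the tree")
        rows = tuple(
            tuple(data[leaf][e] for e in tree.edges) for leaf in tree.leaves
        )
        return cls(tree.leaves, tree.edges, rows)


@dataclass(frozen=True)
class IndexScoreVector:
    """Per-leaf scores ``phi(x)``; for a valid index they sum to PD(T, l)."""

    leaf_order: Tuple[str, ...]
    values: Tuple[Number, ...]

    def __getitem__(self, leaf: str) -> Number:
        return self.values[self.leaf_order.index(leaf)]

    def as_dict(self) -> Dict[str, Number]:
        return dict(zip(self.leaf_order, self.values))

    @property
    def total(self) -> Number:
        return sum(self.values, Fraction(0))

    def __iter__(self):
        return iter(zip(self.leaf_order, self.values))


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of allocation-function / diversity-index validation.

    ``violations`` holds tuples ``(rule, edge, subject, detail)`` with
    ``rule`` one of ``nonneg``, ``column_sum``, ``DI1``, ``pendant``,
    ``DI2``.
    """

    is_allocation: bool
    is_diversity_index: bool
    violations: Tuple[Tuple[str, str, str, str], ...] = ()

    def to_dict(self) -> dict:
        return {
            "is_allocation": self.is_allocation,
            "is_diversity_index": self.is_diversity_index,
            "violations": [list(v) for v in self.violations],
        }


def _check_orders(matrix: CoefficientMatrix, tree: RootedTree) -> None:
    if matrix.leaf_order != tree.leaves or matrix.edge_order != tree.edges:
        raise MatrixShapeError(
            "matrix leaf/edge order does not match the tree's canonical order"
        )


# ---------------------------------------------------------------------------
# Built-in indices
# ---------------------------------------------------------------------------


def fp_matrix(tree: RootedTree) -> CoefficientMatrix:
    """Fair Proportion coefficients: gamma(x, e) = 1/|c_T(e)| for x below e."""
    rows = []
    for x in tree.leaves:
        on_path = set(tree.root_path(x))
        rows.append(
            tuple(
                Fraction(1, len(tree.cluster(e))) if e in on_path else Fraction(0)
                for e in tree.edges
            )
        )
    return CoefficientMatrix(tree.leaves, tree.edges, tuple(rows))


def es_matrix(tree: RootedTree) -> CoefficientMatrix:
    """Equal-Splits coefficients: gamma(x, e) = 1/Pi(e, x) for x below e,
    where Pi(e, x) multiplies the out-degrees of the interior vertices on
    the path from e's terminal vertex to x (Pi = 1 for the pendant edge)."""
    rows = []
    for x in tree.leaves:
        path = tree.root_path(x)
        row = {e: Fraction(0) for e in tree.edges}
        # walk from the pendant edge upwards; Pi multiplies the out-degrees
        # of the terminal vertices of the interior edges at or below e
        pi = Fraction(1)
        for e in reversed(path):
            if tree.children(e):
                pi *= len(tree.children(e))
                row[e] = 1 / pi
            else:
                row[e] = Fraction(1)
        rows.append(tuple(row[e] for e in tree.edges))
    return CoefficientMatrix(tree.leaves, tree.edges, tuple(rows))


def uniform_matrix(tree: RootedTree) -> CoefficientMatrix:
    """The uniform allocation: every coefficient equals 1/n.  A valid
    allocation function, but not a diversity index (it ignores descent)."""
    n = tree.n_leaves
    row = tuple(Fraction(1, n) for _ in tree.edges)
    return CoefficientMatrix(tree.leaves, tree.edges, tuple(row for _ in tree.leaves))


# ---------------------------------------------------------------------------
# Evaluation and validation
# ---------------------------------------------------------------------------


def evaluate(
    matrix: CoefficientMatrix,
    tree: RootedTree,
    lengths: Optional[Mapping[EdgeRef, Number]] = None,
) -> IndexScoreVector:
    """Index score vector v = A l: ``score(x) = sum_e gamma(x, e) l(e)``.

    Exact (Fraction) when both coefficients and lengths are rational.
    """
    _check_orders(matrix, tree)
    lens = [
        (lengths[e] if lengths is not None else tree.length(e)) for e in tree.edges
    ]
    values = tuple(
        sum((g * l for g, l in zip(row, lens) if g != 0), Fraction(0))
        for row in matrix.rows
    )
    return IndexScoreVector(tree.leaves, values)


def check_allocation(
    matrix: CoefficientMatrix, tree: RootedTree, tol: float = DEFAULT_TOL
) -> ValidationReport:
    """Allocation-function check: non-negative entries, unit column sums."""
    _check_orders(matrix, tree)
    violations: List[Tuple[str, str, str, str]] = []
    for j, e in enumerate(tree.edges):
        col = [row[j] for row in matrix.rows]
        for x, g in zip(tree.leaves, col):
            negative = g < 0 if all_exact([g]) else g < -tol
            if negative:
                violations.append(
                    ("nonneg", e, x, f"gamma({x},{e}) = {format_number(g)} < 0")
                )
        s = sum(col, Fraction(0))
        if not near(s, Fraction(1), tol):
            violations.append(
                ("column_sum", e, "", f"column sum {format_number(s)} != 1")
            )
    ok = not violations
    return ValidationReport(ok, False, tuple(violations))


def check_diversity_index(
    matrix: CoefficientMatrix, tree: RootedTree, tol: float = DEFAULT_TOL
) -> ValidationReport:
    """Full diversity-index check: allocation conditions, descent (DI1),
    pendant columns, and neutrality (DI2) via canonical position matching."""
    base = check_allocation(matrix, tree, tol)
    violations = list(base.violations)

    # DI1: zero outside the cluster
    for j, e in enumerate(tree.edges):
        cluster = tree.cluster(e)
        for i, x in enumerate(tree.leaves):
            g = matrix.rows[i][j]
            if x not in cluster and not near(g, Fraction(0), tol):
                violations.append(
                    ("DI1", e, x, f"gamma({x},{e}) = {format_number(g)} but {x} "
                                  f"is not descended from {e}")
                )

    # pendant columns: single 1 at the incident leaf
    for j, e in enumerate(tree.edges):
        if tree.is_pendant_edge(e):
            g = matrix.get(e, e)
            if not near(g, Fraction(1), tol):
                violations.append(
                    ("pendant", e, e, f"gamma({e},{e}) = {format_number(g)} != 1")
                )

    # DI2: coefficients are a function of the shape of P_e; equal in
    # corresponding positions.  Key each edge's coefficients by the position
    # signature of each leaf inside P_e; edges with equal P_e shapes must
    # induce identical signature -> coefficient maps (which also forces
    # constancy on orbits within a single edge).
    by_shape: Dict[str, Tuple[EdgeRef, Dict[Tuple[str, ...], Number]]] = {}
    for e in tree.edges:
        sig_map: Dict[Tuple[str, ...], Number] = {}
        ok = True
        for x in sorted(tree.cluster(e)):
            sig = position_signature(tree, e, x)
            g = matrix.get(x, e)
            if sig in sig_map:
                if not near(sig_map[sig], g, tol):
                    violations.append(
                        ("DI2", e, x,
                         f"gamma({x},{e}) differs within its symmetry orbit")
                    )
                    ok = False
            else:
                sig_map[sig] = g
        if not ok:
            continue
        code = tree.shape_code(e)
        if code in by_shape:
            ref_edge, ref_map = by_shape[code]
            for sig, g in sig_map.items():
                if not near(ref_map[sig], g, tol):
                    violations.append(
                        ("DI2", e, ref_edge,
                         "coefficient pattern differs between edges "
                         f"{e} and {ref_edge} with equal pendant-subtree shape")
                    )
        else:
            by_shape[code] = (e, sig_map)

    is_alloc = base.is_allocation
    is_di = is_alloc and not violations
    return ValidationReport(is_alloc, is_di, tuple(violations))


def convex_combine(
    matrices: Sequence[CoefficientMatrix],
    weights: Sequence[Number],
    tol: float = 1e-12,
) -> CoefficientMatrix:
    """Entrywise convex combination of coefficient matrices.

    A convex combination of diversity indices is again a diversity index,
    so the space of index score vectors is convex.
    """
    if len(matrices) != len(weights) or not matrices:
        raise ValueError("need matching, non-empty matrices and weights")
    first = matrices[0]
    for m in matrices[1:]:
        if m.leaf_order != first.leaf_order or m.edge_order != first.edge_order:
            raise MatrixShapeError("matrices have mismatched orders")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    total = sum(weights, Fraction(0))
    if not near(total, Fraction(1), tol):
        raise ValueError(f"weights must sum to 1 (got {total})")
    rows = tuple(
        tuple(
            sum((w * m.rows[i][j] for w, m in zip(weights, matrices)), Fraction(0))
            for j in range(len(first.edge_order))
        )
        for i in range(len(first.leaf_order))
    )
    return CoefficientMatrix(first.leaf_order, first.edge_order, rows)
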