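"""Rooted phylogenetic X-trees with positive branch lengths.

The central object is :class:`RootedTree`: a rooted tree whose edges are
directed away from the root, whose leaves carry unique taxon labels, and
whose every non-leaf vertex has out-degree at least two (the single-vertex
tree on one taxon is also allowed).  Edges are identified by their terminal
(child) vertex, so an "edge reference" throughout this package is simply a
vertex name.

Trees are immutable.  On construction the children of every vertex are put
into a canonical order (by subtree shape code, ties broken by the sorted
leaf-label set), which makes vertex auto-naming, Newick output, ratio
positions and corner enumeration reproducible across runs.

Branch lengths are parsed as exact :class:`fractions.Fraction` values
(every decimal literal is a rational number), so downstream identities such
as conservation of phylogenetic diversity hold exactly.
"""

from __future__ import annotations

import logging
import re
from fractions import Fraction
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

from ._exact import Number

logger = logging.getLogger("pdspace")

#: An edge is referred to by the name of its terminal (child) vertex.
EdgeRef = str

LEAF_CODE = "L"


class NewickParseError(ValueError):
    """Malformed Newick input; ``position`` is the offending character index."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


class TreeValidationError(ValueError):
    """The described graph is not a valid rooted phylogenetic tree."""


class RootedTree:
    """A rooted phylogenetic tree with labelled leaves and positive lengths.

    Parameters
    ----------
    root:
        Name of the root vertex.
    children:
        Map from vertex name to the tuple of its children.  Vertices that do
        not appear as keys (or map to an empty tuple) are leaves.
    lengths:
        Map from non-root vertex name to the (positive) length of its
        parent edge.  Every non-root vertex must be present.
    """

    __slots__ = (
        "root",
        "_children",
        "_parent",
        "_length",
        "_preorder",
        "_leaves",
        "_edges",
        "_codes",
        "_nleaves",
        "_cluster",
    )

    def __init__(
        self,
        root: str,
        children: Mapping[str, Sequence[str]],
        lengths: Mapping[str, Number],
    ):
        children = {v: tuple(cs) for v, cs in children.items() if cs}
        vertices = {root}
        parent: Dict[str, str] = {}
        for v, cs in children.items():
            for c in cs:
                if c in parent:
                    raise TreeValidationError(f"vertex {c!r} has two parents")
                parent[c] = v
                vertices.add(c)
            vertices.add(v)
        if root in parent:
            raise TreeValidationError("root vertex has a parent")
        for v in children:
            if v != root and v not in parent:
                raise TreeValidationError(f"vertex {v!r} is not reachable from the root")
        for v, cs in children.items():
            if len(cs) == 1:
                raise TreeValidationError(
                    f"vertex {v!r} has out-degree 1; every non-leaf vertex "
                    "must have out-degree at least 2"
                )
        # reachability (guards against cycles referencing the root component)
        seen = set()
        stack = [root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise TreeValidationError("cycle detected")
            seen.add(v)
            stack.extend(children.get(v, ()))
        if seen != vertices:
            raise TreeValidationError("graph is not connected")

        length: Dict[str, Number] = {}
        for v in parent:
            if v not in lengths:
                raise TreeValidationError(f"edge above {v!r} has no length")
            val = lengths[v]
            if not val > 0:
                raise TreeValidationError(
                    f"edge above {v!r} has non-positive length {val!r}"
                )
            length[v] = val

        leaf_labels = [v for v in vertices if v not in children]
        if len(set(leaf_labels)) != len(leaf_labels):  # pragma: no cover
            raise TreeValidationError("duplicate leaf labels")

        self.root = root
        self._parent = parent
        self._length = length

        # canonical shape codes, bottom-up (iterative postorder)
        codes: Dict[str, str] = {}
        clusters: Dict[str, Tuple[str, ...]] = {}
        for v in self._postorder_from(root, children):
            cs = children.get(v, ())
            if not cs:
                codes[v] = LEAF_CODE
                clusters[v] = (v,)
            else:
                codes[v] = "(" + ",".join(sorted(codes[c] for c in cs)) + ")"
                merged: list[str] = []
                for c in cs:
                    merged.extend(clusters[c])
                clusters[v] = tuple(sorted(merged))
        # canonical child order: by shape code, then by leaf-label set
        self._children = {
            v: tuple(sorted(cs, key=lambda c: (codes[c], clusters[c])))
            for v, cs in children.items()
        }
        self._codes = codes
        self._cluster = {v: frozenset(clusters[v]) for v in vertices}

        order: list[str] = []
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self._children.get(v, ())))
        self._preorder = tuple(order)
        self._leaves = tuple(v for v in order if v not in self._children)
        self._edges = tuple(v for v in order if v != root)
        self._nleaves = {v: len(self._cluster[v]) for v in vertices}

    # -- basic structure ---------------------------------------------------

    @property
    def vertices(self) -> Tuple[str, ...]:
        """All vertices in canonical preorder (root first)."""
        return self._preorder

    @property
    def leaves(self) -> Tuple[str, ...]:
        """Leaf labels in canonical preorder."""
        return self._leaves

    @property
    def edges(self) -> Tuple[EdgeRef, ...]:
        """All edges (named by terminal vertex) in canonical preorder."""
        return self._edges

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def children(self, v: str) -> Tuple[str, ...]:
        self._require_vertex(v)
        return self._children.get(v, ())

    def parent(self, v: str) -> Optional[str]:
        self._require_vertex(v)
        return self._parent.get(v)

    def is_leaf(self, v: str) -> bool:
        self._require_vertex(v)
        return v not in self._children

    def is_pendant_edge(self, e: EdgeRef) -> bool:
        self._require_edge(e)
        return e not in self._children

    def length(self, e: EdgeRef) -> Number:
        self._require_edge(e)
        return self._length[e]

    @property
    def lengths(self) -> Dict[EdgeRef, Number]:
        return dict(self._length)

    def shape_code(self, v: str) -> str:
        """Canonical (AHU-style) code of the subtree shape rooted at ``v``."""
        self._require_vertex(v)
        return self._codes[v]

    def leaf_count(self, v: str) -> int:
        """Number of leaves descended from ``v`` (1 for a leaf)."""
        self._require_vertex(v)
        return self._nleaves[v]

    def _require_vertex(self, v: str) -> None:
        if v not in self._cluster:
            raise LookupError(f"unknown vertex {v!r}")

    def _require_edge(self, e: EdgeRef) -> None:
        if e not in self._length:
            raise LookupError(f"unknown edge {e!r}")

    @staticmethod
    def _postorder_from(root, children) -> Iterable[str]:
        out = []
        stack = [root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(children.get(v, ()))
        return reversed(out)

    # -- structural primitives --------------------------------------------

    def total_pd(self) -> Number:
        """Phylogenetic diversity PD(T, l): the sum of all edge lengths."""
        return sum(self._length.values(), Fraction(0))

    def cluster(self, e: EdgeRef) -> frozenset:
        """The set of leaf labels descended from edge ``e``."""
        self._require_edge(e)
        return self._cluster[e]

    def root_path(self, leaf: str) -> Tuple[EdgeRef, ...]:
        """Edges from the root to ``leaf``, in order (last is the pendant edge)."""
        if leaf not in self._cluster or leaf in self._children:
            raise LookupError(f"unknown leaf {leaf!r}")
        path = []
        v = leaf
        while v != self.root:
            path.append(v)
            v = self._parent[v]
        return tuple(reversed(path))

    def pendant_subtree(self, e: EdgeRef) -> "RootedTree":
        """The pendant subtree P_e obtained by deleting edge ``e``."""
        self._require_edge(e)
        sub_children: Dict[str, Tuple[str, ...]] = {}
        sub_lengths: Dict[str, Number] = {}
        stack = [e]
        while stack:
            v = stack.pop()
            cs = self._children.get(v, ())
            if cs:
                sub_children[v] = cs
            for c in cs:
                sub_lengths[c] = self._length[c]
                stack.append(c)
        return RootedTree(e, sub_children, sub_lengths)

    def contract_edge(self, e: EdgeRef) -> "RootedTree":
        """The tree T/e: collapse interior edge ``e`` into its parent vertex.

        The children of ``e``'s terminal vertex are re-attached to its
        initial vertex; all other lengths and the leaf set are unchanged.
        """
        self._require_edge(e)
        if e not in self._children:
            raise ValueError("cannot contract a pendant edge")
        p = self._parent[e]
        new_children = dict(self._children)
        kept = tuple(c for c in new_children[p] if c != e)
        new_children[p] = kept + self._children[e]
        del new_children[e]
        new_lengths = {v: l for v, l in self._length.items() if v != e}
        return RootedTree(self.root, new_children, new_lengths)

    def with_lengths(self, lengths: Mapping[EdgeRef, Number]) -> "RootedTree":
        """Copy of this tree with the given edge length assignment."""
        return RootedTree(self.root, self._children, dict(lengths))

    def unit_lengths(self) -> "RootedTree":
        return self.with_lengths({e: Fraction(1) for e in self._edges})

    # -- comparison / output ----------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, RootedTree):
            return NotImplemented
        return (
            self.root == other.root
            and self._children == other._children
            and self._length == other._length
        )

    def __hash__(self):  # pragma: no cover
        return hash((self.root, tuple(sorted(self._children.items()))))

    def same_shape(self, other: "RootedTree") -> bool:
        """True iff the two trees have the same tree shape (ignore labels)."""
        return self._codes[self.root] == other._codes[other.root]

    def __repr__(self) -> str:
        return f"<RootedTree {self.n_leaves} leaves, {len(self._edges)} edges>"

    def to_newick(self) -> str:
        return write_newick(self)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"[^\s(),:;]+")
_NUMBER_RE = re.compile(r"[+-]?(?:\d+(?:\.\d*)?|\.\d+)(?:[eE][+-]?\d+)?")


def parse_newick(text: str) -> RootedTree:
    """Parse a single rooted Newick tree.

    Branch lengths are optional and default to 1 (with a logged warning when
    the input mixes explicit and missing lengths); they are read as exact
    rationals.  A length attached to the root token is rejected.  Internal
    vertex labels are preserved; unlabelled internal vertices are named
    ``v<i>`` by canonical preorder index.
    """
    pos = 0
    n = len(text)
    anon_counter = 0

    def skip_ws():
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def parse_subtree():
        # returns (label_or_None, children_list, length_or_None)
        nonlocal pos, anon_counter
        skip_ws()
        if pos >= n:
            raise NewickParseError("unexpected end of input", pos)
        children = []
        label = None
        if text[pos] == "(":
            pos += 1
            while True:
                children.append(parse_subtree())
                skip_ws()
                if pos >= n:
                    raise NewickParseError("unterminated '('", pos)
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise NewickParseError(
                    f"expected ',' or ')', found {text[pos]!r}", pos
                )
            skip_ws()
            m = _LABEL_RE.match(text, pos)
            if m:
                label = m.group(0)
                pos = m.end()
        else:
            m = _LABEL_RE.match(text, pos)
            if not m:
                raise NewickParseError(
                    f"expected a label or '(', found {text[pos]!r}", pos
                )
            label = m.group(0)
            pos = m.end()
        skip_ws()
        length = None
        if pos < n and text[pos] == ":":
            pos += 1
            skip_ws()
            m = _NUMBER_RE.match(text, pos)
            if not m:
                raise NewickParseError("expected a branch length after ':'", pos)
            length = Fraction(m.group(0))
            pos = m.end()
        return [label, children, length]

    node = parse_subtree()
    skip_ws()
    if pos >= n or text[pos] != ";":
        raise NewickParseError("expected ';' at end of tree", pos)
    pos += 1
    skip_ws()
    if pos != n:
        raise NewickParseError("trailing characters after ';'", pos)

    if node[2] is not None:
        raise TreeValidationError(
            "a branch length on the root token is not allowed "
            "(rooted trees here have no root edge)"
        )
    # collapse a redundant unary root wrapper: "(subtree);" with no label and
    # no length on the inner edge
    while node[0] is None and len(node[1]) == 1 and node[1][0][2] is None:
        node = node[1][0]
    if node[2] is not None:
        raise TreeValidationError("a branch length on the root token is not allowed")

    # flatten into dicts, naming anonymous internals with placeholders
    children_map: Dict[str, Tuple[str, ...]] = {}
    lengths: Dict[str, Number] = {}
    missing_lengths = 0
    explicit_lengths = 0
    seen_labels = set()

    def realise(nd) -> str:
        nonlocal anon_counter, missing_lengths, explicit_lengths
        label, kids, _ = nd
        if label is None:
            if not kids:
                raise NewickParseError("leaf without a label", 0)
            name = f"\x00anon{anon_counter}"
            anon_counter += 1
        else:
            name = label
            if name in seen_labels:
                raise TreeValidationError(f"duplicate label {name!r}")
            seen_labels.add(name)
        kid_names = []
        for kid in kids:
            kn = realise(kid)
            kid_names.append(kn)
            if kid[2] is None:
                lengths[kn] = Fraction(1)
                missing_lengths += 1
            else:
                lengths[kn] = kid[2]
                explicit_lengths += 1
        if kid_names:
            children_map[name] = tuple(kid_names)
        return name

    root = realise(node)
    if missing_lengths and explicit_lengths:
        logger.warning(
            "Newick input mixes explicit and missing branch lengths; "
            "%d missing length(s) defaulted to 1", missing_lengths,
        )
    tree = RootedTree(root, children_map, lengths)
    # rename anonymous internals by canonical preorder index
    rename = {}
    used = set(v for v in tree.vertices if not v.startswith("\x00anon"))
    for idx, v in enumerate(tree.vertices):
        if v.startswith("\x00anon"):
            name = f"v{idx}"
            while name in used:
                name = "v" + name
            used.add(name)
            rename[v] = name
    if not rename:
        return tree
    remap = lambda v: rename.get(v, v)
    children_map = {
        remap(v): tuple(remap(c) for c in cs) for v, cs in children_map.items()
    }
    lengths = {remap(v): l for v, l in lengths.items()}
    return RootedTree(remap(root), children_map, lengths)


def _format_length(value: Number) -> str:
    if isinstance(value, (Fraction, int)):
        f = Fraction(value)
        if f.denominator == 1:
            return str(f.numerator)
        # terminating decimal?
        den = f.denominator
        twos = fives = 0
        while den % 2 == 0:
            den //= 2
            twos += 1
        while den % 5 == 0:
            den //= 5
            fives += 1
        digits = max(twos, fives)
        if den == 1 and digits <= 12:
            scaled = f.numerator * 10**digits // f.denominator
            s = str(abs(scaled)).rjust(digits + 1, "0")
            sign = "-" if scaled < 0 else ""
            return f"{sign}{s[:-digits]}.{s[-digits:]}"
        return repr(float(f))
    return repr(value)


def write_newick(tree: RootedTree) -> str:
    """Serialise a tree to Newick (children in canonical order).

    Round-trip stable: ``parse_newick(write_newick(t)) == t``.
    """

    def render(v: str) -> str:
        cs = tree.children(v)
        if not cs:
            core = v
        else:
            core = "(" + ",".join(
                render(c) + ":" + _format_length(tree.length(c)) for c in cs
            ) + ")" + v
        return core

    return render(tree.root) + ";"


def total_pd(tree: RootedTree) -> Number:
    """Phylogenetic diversity: the sum of all edge lengths (0 for one vertex)."""
    return tree.total_pd()
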