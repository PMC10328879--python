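"""Worked example trees and a seeded random-tree generator.

The named fixtures are the small trees used throughout this package's
documentation and tests: the five-leaf caterpillar ``cat5`` (whose index
space is a two-dimensional quadrilateral), trees with matched pendant
subtrees exercising the neutrality condition, one- and zero-dimensional
five-leaf shapes, and a hominoid (great ape + gibbon) tree with nine free
symmetry classes (classical index-space dimension nine).

All fixtures have unit branch lengths.
"""

from __future__ import annotations

import random
import re
from importlib import resources
from typing import Callable, Optional

from ._exact import Number
from .tree import RootedTree, parse_newick

# Named trees shipped as Newick files under ``pdspace/data/``.  The
# hominoid (great apes + gibbons) tree is a *stylised* transcription with
# unit lengths: built to exhibit the documented symmetry-class structure
# (nine one-degree-of-freedom equivalence classes, among them a two-member
# cherry+triple class and a three-member leaf+cherry class, two distinct
# cherry+five-leaf classes, and two zero-degree-of-freedom classes), not
# to settle species-level phylogeny.
_FILE_FIXTURES = ("cat5", "fig2", "fig3", "fig4a", "fig4b", "hominoid")


def _load_named(name: str) -> RootedTree:
    text = resources.files("pdspace").joinpath(f"data/{name}.nwk").read_text()
    return parse_newick(text)


def cherry() -> RootedTree:
    return parse_newick("(x1:1,x2:1);")


def caterpillar(n: int) -> RootedTree:
    """Rooted caterpillar on ``n`` leaves, unit lengths."""
    if n < 1:
        raise ValueError("need n >= 1")
    if n == 1:
        return parse_newick("x1;")
    core = "(x1:1,x2:1)"
    for i in range(3, n + 1):
        core = f"({core}:1,x{i}:1)"
    return parse_newick(core + ";")


def star(n: int) -> RootedTree:
    """Star tree: the root with ``n`` leaf children, unit lengths."""
    if n < 1:
        raise ValueError("need n >= 1")
    if n == 1:
        return parse_newick("x1;")
    return parse_newick("(" + ",".join(f"x{i}:1" for i in range(1, n + 1)) + ");")


def balanced8() -> RootedTree:
    return parse_newick(
        "(((x1:1,x2:1):1,(x3:1,x4:1):1):1,((x5:1,x6:1):1,(x7:1,x8:1):1):1);"
    )


_NAMED: dict[str, Callable[[], RootedTree]] = {
    **{name: (lambda n=name: _load_named(n)) for name in _FILE_FIXTURES},
    "cherry": cherry,
    "balanced8": balanced8,
}

_PARAM_RE = re.compile(r"^(star|caterpillar)\((\d+)\)$")

FIXTURE_NAMES = tuple(_NAMED) + ("star(n)", "caterpillar(n)")


def make_fixture(name: str) -> RootedTree:
    """Deterministic fixture tree by name.

    Known names: ``cat5, fig2, fig3, fig4a, fig4b, hominoid, cherry,
    balanced8`` and parametrised ``star(n)`` / ``caterpillar(n)``.
    """
    if name in _NAMED:
        return _NAMED[name]()
    m = _PARAM_RE.match(name.replace(" ", ""))
    if m:
        n = int(m.group(2))
        return star(n) if m.group(1) == "star" else caterpillar(n)
    raise LookupError(
        f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}"
    )


def random_tree(
    n: int,
    seed: int,
    multifurcation_prob: float = 0.0,
    length_sampler: Optional[Callable[[random.Random], Number]] = None,
) -> RootedTree:
    """Seeded random rooted tree on ``n`` leaves ``x1..xn``.

    A binary tree is grown by sequential random leaf attachment (each new
    leaf subdivides a uniformly chosen edge); each interior non-root edge
    of the result is then contracted independently with probability
    ``multifurcation_prob``.  Unit lengths, unless ``length_sampler`` is
    given (called once per edge with the generator's Random instance).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if not 0 <= multifurcation_prob < 1:
        raise ValueError("multifurcation_prob must be in [0, 1)")
    rng = random.Random(seed)
    if n == 1:
        return parse_newick("x1;")

    # grow nested [label, children] structure
    def new_leaf(i):
        return [f"x{i}", []]

    root = ["", [new_leaf(1), new_leaf(2)]]
    # edge list as (parent_node, child_index)
    edges = [(root, 0), (root, 1)]
    for i in range(3, n + 1):
        parent, idx = rng.choice(edges)
        old = parent[1][idx]
        mid = ["", [old, new_leaf(i)]]
        parent[1][idx] = mid
        edges.append((mid, 0))
        edges.append((mid, 1))
        # the slot (parent, idx) now refers to mid's edge; the edge into old
        # is (mid, 0) and the new pendant edge is (mid, 1) — all distinct.

    def to_newick(node) -> str:
        label, kids = node
        if not kids:
            return f"{label}:1"
        return "(" + ",".join(to_newick(k) for k in kids) + "):1"

    text = "(" + ",".join(to_newick(k) for k in root[1]) + ");"
    tree = parse_newick(text)

    if multifurcation_prob > 0:
        interior = [e for e in tree.edges if not tree.is_pendant_edge(e)]
        doomed = [e for e in interior if rng.random() < multifurcation_prob]
        # vertex names are stable under contraction, so contract by name
        for e in doomed:
            tree = tree.contract_edge(e)

    if length_sampler is not None:
        tree = tree.with_lengths({e: length_sampler(rng) for e in tree.edges})
    return tree
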