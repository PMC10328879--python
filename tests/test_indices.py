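"""Coefficient matrices: FP/ES/uniform, evaluation, validation, combination."""

import itertools
from fractions import Fraction
from math import factorial

import pytest

from pdspace import (
    CoefficientMatrix,
    check_allocation,
    check_diversity_index,
    convex_combine,
    es_matrix,
    evaluate,
    flow_scores,
    fp_matrix,
    make_fixture,
    parse_newick,
    sample_index,
    score_bounds,
    total_pd,
    uniform_matrix,
)

from conftest import random_trees


class TestBuiltInMatrices:
    def test_fp_coefficients(self, cat5, fig3):
        fp = fp_matrix(fig3)
        assert fp.get("x3", "e7") == Fraction(1, 3)
        assert fp_matrix(cat5).get("x3", "h") == Fraction(1, 4)

    def test_es_coefficients(self, cat5, fig3):
        assert es_matrix(fig3).get("x3", "e7") == Fraction(1, 2)
        assert es_matrix(cat5).get("x1", "h") == Fraction(1, 8)

    def test_pendant_columns_are_indicator_vectors(self, cat5):
        for m in (fp_matrix(cat5), es_matrix(cat5)):
            for e in cat5.edges:
                if cat5.is_pendant_edge(e):
                    col = m.column(e)
                    assert sorted(col) == [0, 0, 0, 0, 1]
                    assert m.get(e, e) == 1

    def test_uniform_is_allocation_but_not_index(self, cat5):
        u = uniform_matrix(cat5)
        assert check_allocation(u, cat5).is_allocation
        report = check_diversity_index(u, cat5)
        assert not report.is_diversity_index
        assert any(v[0] == "DI1" for v in report.violations)


class TestEvaluate:
    def test_cat5_scores(self, cat5):
        fp = evaluate(fp_matrix(cat5), cat5)
        assert fp["x3"] == Fraction(19, 12)
        es = evaluate(es_matrix(cat5), cat5)
        assert es["x1"] == Fraction(15, 8)

    def test_fig4a_symbolic_pattern(self, fig4a):
        # score(x3) = alpha*l(g) + l(c) with alpha = 1/4 for FP
        lengths = {e: Fraction(1) for e in fig4a.edges}
        lengths["g"] = Fraction(3)
        lengths["x3"] = Fraction(5, 2)
        fp = fp_matrix(fig4a)
        scores = evaluate(fp, fig4a, lengths)
        alpha = fp.get("x3", "g")
        assert scores["x3"] == alpha * lengths["g"] + lengths["x3"]

    def test_conservation_of_pd(self):
        for t in random_trees(60, n_max=10, multi=0.2, lengths=True):
            for m in (fp_matrix(t), es_matrix(t), uniform_matrix(t)):
                assert evaluate(m, t).total == total_pd(t)

    def test_linearity_in_lengths(self):
        for t in random_trees(20, n_max=8, lengths=True):
            m = fp_matrix(t)
            l1 = {e: t.length(e) for e in t.edges}
            l2 = {e: Fraction(3, 2) * t.length(e) + 1 for e in t.edges}
            s, u = Fraction(2, 3), Fraction(5)
            blended = {e: s * l1[e] + u * l2[e] for e in t.edges}
            left = evaluate(m, t, blended)
            a, b = evaluate(m, t, l1), evaluate(m, t, l2)
            for x in t.leaves:
                assert left[x] == s * a[x] + u * b[x]

    def test_order_mismatch_rejected(self, cat5, fig3):
        with pytest.raises(ValueError):
            evaluate(fp_matrix(fig3), cat5)


class TestValidation:
    def test_negative_coefficients_rejected(self):
        # two-leaf allocation x -> 2l(a)+2l(b), y -> -l(a)-l(b)
        t = parse_newick("(x:1,y:1);")
        m = CoefficientMatrix(
            t.leaves,
            t.edges,
            tuple(
                tuple(Fraction(2) if leaf == "x" else Fraction(-1) for _ in t.edges)
                for leaf in t.leaves
            ),
        )
        report = check_allocation(m, t)
        assert not report.is_allocation
        assert any(v[0] == "nonneg" for v in report.violations)

    def test_fp_es_pass_on_random_trees(self):
        for t in random_trees(100, n_max=9, multi=0.25):
            for m in (fp_matrix(t), es_matrix(t)):
                report = check_diversity_index(m, t)
                assert report.is_diversity_index, report.violations

    def test_fig2_neutrality_equalities_enforced(self, fig2):
        fp = fp_matrix(fig2)
        # DI2 on this tree forces these coefficient equalities
        assert fp.get("x5", "b") == fp.get("x6", "b") == fp.get("x1", "c") == fp.get("x2", "c")
        assert fp.get("x7", "b") == fp.get("x3", "c")
        assert fp.get("x5", "d") == fp.get("x6", "d") == fp.get("x1", "e") == fp.get("x2", "e")
        # breaking one of them is reported as a DI2 violation
        rows = [list(r) for r in fp.rows]
        i7 = fp.leaf_order.index("x7")
        i3 = fp.leaf_order.index("x3")
        jb = fp.edge_order.index("b")
        jc = fp.edge_order.index("c")
        eps = Fraction(1, 10)
        rows[i7][jb] += eps
        i5 = fp.leaf_order.index("x5")
        rows[i5][jb] -= eps  # keep the column sum at 1
        broken = CoefficientMatrix(fp.leaf_order, fp.edge_order, tuple(map(tuple, rows)))
        report = check_diversity_index(broken, fig2)
        assert not report.is_diversity_index
        assert any(v[0] == "DI2" for v in report.violations)

    def test_score_bounds_hold_for_builtin_and_sampled(self):
        for t in random_trees(20, n_min=3, n_max=9, multi=0.2):
            matrices = [fp_matrix(t), es_matrix(t)]
            scores_list = [evaluate(m, t) for m in matrices]
            for s in range(10):
                scheme = sample_index(t, seed=1000 + s)
                scores_list.append(flow_scores(t, scheme))
            for scores in scores_list:
                for x in t.leaves:
                    lo, hi = score_bounds(t, x)
                    assert lo <= scores[x] <= hi


class TestConvexCombine:
    def test_midpoint_of_fp_and_es(self, cat5):
        half = Fraction(1, 2)
        mid = convex_combine([fp_matrix(cat5), es_matrix(cat5)], [half, half])
        assert check_diversity_index(mid, cat5).is_diversity_index
        fp, es = evaluate(fp_matrix(cat5), cat5), evaluate(es_matrix(cat5), cat5)
        got = evaluate(mid, cat5)
        for x in cat5.leaves:
            assert got[x] == (fp[x] + es[x]) / 2

    def test_degenerate_weights_identity(self, cat5):
        m = convex_combine([fp_matrix(cat5), es_matrix(cat5)], [Fraction(1), Fraction(0)])
        assert m.rows == fp_matrix(cat5).rows

    def test_bad_weights_rejected(self, cat5):
        with pytest.raises(ValueError):
            convex_combine([fp_matrix(cat5)], [Fraction(1, 2)])


class TestTsvRoundTrip:
    def test_round_trip(self, cat5):
        m = es_matrix(cat5)
        back = CoefficientMatrix.from_tsv(m.to_tsv(), cat5)
        assert back.rows == m.rows


def shapley_values(tree):
    """Brute-force Shapley value of the PD coalition game.

    v(S) = PD of the minimal root-spanning subtree of S: the sum of lengths
    of edges with at least one member of S below them.
    """
    leaves = tree.leaves
    n = len(leaves)

    def v(coalition):
        if not coalition:
            return Fraction(0)
        return sum(
            (Fraction(tree.length(e)) for e in tree.edges
             if tree.cluster(e) & coalition),
            Fraction(0),
        )

    values = {}
    for x in leaves:
        others = [y for y in leaves if y != x]
        acc = Fraction(0)
        for r in range(len(others) + 1):
            for combo in itertools.combinations(others, r):
                s = frozenset(combo)
                weight = Fraction(
                    factorial(len(s)) * factorial(n - len(s) - 1), factorial(n)
                )
                acc += weight * (v(s | {x}) - v(s))
        values[x] = acc
    return values


class TestShapleyOracle:
    @pytest.mark.parametrize(
        "name", ["cat5", "fig2", "fig3", "fig4a", "fig4b", "cherry"]
    )
    def test_fp_equals_shapley_value(self, name):
        t = make_fixture(name)
        assert t.n_leaves <= 7
        fp = evaluate(fp_matrix(t), t)
        expected = shapley_values(t)
        for x in t.leaves:
            assert fp[x] == expected[x]
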