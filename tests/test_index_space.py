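"""Corners, Caratheodory bases, coordinates, sampling, and family properties."""

from fractions import Fraction

import pytest

from pdspace import (
    NotInSpanError,
    OutsideHullError,
    caratheodory_basis,
    check_family_properties,
    corner_coordinates,
    corner_count,
    corner_indices,
    es_matrix,
    evaluate,
    flow_scores,
    fp_matrix,
    has_singleton_free_classes,
    list_corners,
    make_fixture,
    ratios_to_matrix,
    sample_index,
    score_bounds,
    space_dimension,
    total_degrees_of_freedom,
    total_pd,
)
from pdspace._exact import exact_rank
from pdspace.index_space import corner_scheme

from conftest import random_trees


CAT5_CORNER_VECTORS = [
    [Fraction(5, 2), Fraction(5, 2), 1, 1, 1],   # kappa: 1:0, 1:0
    [Fraction(3, 2), Fraction(3, 2), 3, 1, 1],   # lambda: 1:0, 0:1
    [2, 2, 1, 2, 1],                             # mu: 0:1, 1:0
    [Fraction(3, 2), Fraction(3, 2), 2, 2, 1],   # nu: 0:1, 0:1
]


class TestCornerIndices:
    def test_cat5_corners_match_printed_vectors(self, cat5):
        corners = list_corners(cat5)
        assert len(corners) == 4
        got = [[c.scores[x] for x in ["x1", "x2", "x3", "x4", "x5"]] for c in corners]
        assert got == CAT5_CORNER_VECTORS

    def test_semi_balanced_tree_has_single_corner(self, fig4b):
        corners = list_corners(fig4b)
        assert len(corners) == 1
        fp = evaluate(fp_matrix(fig4b), fig4b)
        es = evaluate(es_matrix(fig4b), fig4b)
        assert corners[0].scores.values == fp.values == es.values

    def test_hominoid_corner_count(self, hominoid):
        assert corner_count(hominoid) == 512
        it = corner_indices(hominoid)
        first = next(it)
        assert first.scores.total == total_pd(hominoid)

    def test_materialisation_cap(self, hominoid):
        with pytest.raises(ValueError):
            list_corners(hominoid, cap=100)
        assert len(list_corners(hominoid, cap=512)) == 512

    def test_corner_scores_saturate_bounds_on_cat5(self, cat5):
        # kappa attains x1's upper bound, lambda x3's, and every corner
        # leaves x5 at its (coincident) bounds
        corners = list_corners(cat5)
        assert corners[0].scores["x1"] == score_bounds(cat5, "x1")[1]
        assert corners[1].scores["x3"] == score_bounds(cat5, "x3")[1]
        for c in corners:
            lo, hi = score_bounds(cat5, "x5")
            assert lo == c.scores["x5"] == hi


class TestCaratheodoryBasis:
    def test_cat5_basis_is_kappa_mu_lambda(self, cat5):
        basis = caratheodory_basis(cat5)
        assert len(basis) == 3
        got = {tuple(b.scores[x] for x in ["x1", "x2", "x3", "x4", "x5"]) for b in basis}
        assert got == {
            tuple(CAT5_CORNER_VECTORS[0]),
            tuple(CAT5_CORNER_VECTORS[1]),
            tuple(CAT5_CORNER_VECTORS[2]),
        }

    def test_semi_balanced_basis_is_fp_alone(self, fig4b):
        basis = caratheodory_basis(fig4b)
        assert len(basis) == 1
        assert basis[0].scores.values == evaluate(fp_matrix(fig4b), fig4b).values

    def test_fig3_basis_has_two_corners(self, fig3):
        assert len(caratheodory_basis(fig3)) == 2

    def test_basis_size_is_dimension_plus_one(self):
        for t in random_trees(30, n_min=3, n_max=9, multi=0.2):
            assert len(caratheodory_basis(t)) == max(1, space_dimension(t) + 1)


class TestCornerCoordinates:
    def test_fp_and_es_positions_on_cat5(self, cat5):
        corners = list_corners(cat5)
        basis = [corners[0], corners[1], corners[2]]  # kappa, lambda, mu
        fp_w = corner_coordinates(evaluate(fp_matrix(cat5), cat5), basis)
        assert fp_w[1:] == (Fraction(7, 24), Fraction(1, 4))
        es_w = corner_coordinates(evaluate(es_matrix(cat5), cat5), basis)
        assert es_w[1:] == (Fraction(9, 24), Fraction(1, 2))

    def test_convex_combination_of_corner_matrices_reproduces_fp(self, cat5):
        from pdspace import convex_combine

        kappa, lam, mu, _ = list_corners(cat5)
        matrices = [ratios_to_matrix(cat5, c.scheme) for c in (kappa, lam, mu)]
        weights = [Fraction(11, 24), Fraction(7, 24), Fraction(1, 4)]
        blended = evaluate(convex_combine(matrices, weights), cat5)
        assert blended.values == evaluate(fp_matrix(cat5), cat5).values

    def test_basis_element_has_unit_weight(self, cat5):
        basis = caratheodory_basis(cat5)
        w = corner_coordinates(basis[0].scores, basis)
        assert w == (Fraction(1), Fraction(0), Fraction(0))

    def test_outside_span_and_hull_detection(self, cat5):
        basis = caratheodory_basis(cat5)
        with pytest.raises(NotInSpanError):
            corner_coordinates([Fraction(9), 0, 0, 0, 0], basis)
        nu = list_corners(cat5)[3].scores  # in span of the quadrilateral,
        # but nu = -kappa + lambda + mu: outside the (kappa,lambda,mu) simplex
        with pytest.raises(OutsideHullError):
            corner_coordinates(nu, basis)

    def test_agrees_with_sympy_least_squares(self, cat5):
        sympy = pytest.importorskip("sympy")
        basis = caratheodory_basis(cat5)
        target = evaluate(es_matrix(cat5), cat5)
        a = sympy.Matrix(
            [[sympy.Rational(b.scores[x]) for b in basis] for x in cat5.leaves]
            + [[1] * len(basis)]
        )
        rhs = sympy.Matrix([sympy.Rational(target[x]) for x in cat5.leaves] + [1])
        expected = a.solve_least_squares(rhs)
        got = corner_coordinates(target, basis)
        assert [sympy.Rational(w) for w in got] == list(expected)

    def test_affine_parametrisation_relative_to_b1(self, cat5):
        # the fourth corner nu is an affine (not convex) combination of the
        # basis: nu = -kappa + lambda + mu
        basis = caratheodory_basis(cat5)
        nu = list_corners(cat5)[3].scores
        w = corner_coordinates(nu, basis, require_convex=False)
        assert sum(w, Fraction(0)) == 1
        assert min(w) < 0

    def test_caratheodory_some_subset_of_corners_suffices(self):
        """Every sampled index is a convex combination of at most d+1
        corners chosen from the corner set (Caratheodory)."""
        import itertools as it

        for name in ["cat5", "fig3", "fig4a", "fig4b"]:
            t = make_fixture(name)
            corners = list_corners(t)
            k = space_dimension(t) + 1
            for s in range(100):
                scores = flow_scores(t, sample_index(t, seed=s))
                found = False
                for subset in it.combinations(corners, min(k, len(corners))):
                    try:
                        w = corner_coordinates(scores, list(subset))
                    except (NotInSpanError, OutsideHullError):
                        continue
                    assert sum(w, Fraction(0)) == 1 and all(x >= 0 for x in w)
                    for leaf in t.leaves:
                        recon = sum(
                            (wi * b.scores[leaf] for wi, b in zip(w, subset)),
                            Fraction(0),
                        )
                        assert recon == scores[leaf]
                    found = True
                    break
                assert found, f"{name}: sample {s} not covered by any corner simplex"

    def test_samples_lie_in_corner_hull_hominoid(self, hominoid):
        """Sampled indices are convex combinations of the 512 corners
        (linear-programming feasibility; scores are multilinear in the
        per-class ratio parameters)."""
        import numpy as np
        from scipy.optimize import linprog

        corners = list_corners(hominoid, cap=512)
        a = np.array([[float(v) for v in c.scores.values] for c in corners]).T
        a = np.vstack([a, np.ones(len(corners))])
        for s in range(5):
            scores = flow_scores(hominoid, sample_index(hominoid, seed=s))
            b = np.array([float(v) for v in scores.values] + [1.0])
            res = linprog(
                np.zeros(len(corners)), A_eq=a, b_eq=b, bounds=(0, None),
                method="highs",
            )
            assert res.status == 0
            assert np.max(np.abs(a @ res.x - b)) < 1e-8


class TestDimensionViaCornerRank:
    """Independent geometric check of the dimension formula.

    The classical class-collapsed count is exact whenever every free
    ``~``-class has a single member; in general the affine rank of the
    corner set is bracketed between the class-collapsed and the per-vertex
    degree-of-freedom totals (a free class whose members sit in unequal
    ancestral contexts contributes extra affine directions).
    """

    @staticmethod
    def corner_affine_rank(t):
        corners = list_corners(t)
        base = corners[0].scores.values
        rows = [
            [Fraction(v) - Fraction(b) for v, b in zip(c.scores.values, base)]
            for c in corners[1:]
        ]
        return exact_rank(rows)

    def test_rank_equals_dimension_for_singleton_free_classes(self):
        checked = 0
        for t in random_trees(200, n_min=2, n_max=10, multi=0.25):
            if has_singleton_free_classes(t):
                assert self.corner_affine_rank(t) == space_dimension(t)
                checked += 1
        assert checked >= 50  # the regime is common at these sizes

    def test_rank_bracketed_by_dof_totals(self):
        for t in random_trees(200, n_min=2, n_max=10, multi=0.25):
            rank = self.corner_affine_rank(t)
            assert space_dimension(t) <= rank <= total_degrees_of_freedom(t)
            assert rank <= max(0, t.n_leaves - 2)

    @pytest.mark.parametrize(
        "name,rank", [("cat5", 2), ("fig3", 1), ("fig4a", 1), ("fig4b", 0)]
    )
    def test_fixture_ranks(self, name, rank):
        assert self.corner_affine_rank(make_fixture(name)) == rank


class TestSampleIndex:
    def test_deterministic(self, cat5):
        a, b = sample_index(cat5, seed=5), sample_index(cat5, seed=5)
        assert a.class_ratios == b.class_ratios

    def test_semi_balanced_gives_unique_fp_point(self, fig4b):
        fp = evaluate(fp_matrix(fig4b), fig4b)
        for s in range(5):
            assert flow_scores(fig4b, sample_index(fig4b, seed=s)).values == fp.values

    def test_samples_inside_corner_hull_projection(self, cat5):
        corners = list_corners(cat5)
        # S(Cat5, 1) projected to (phi(x3), phi(x4)) is the quadrilateral
        # with vertices kappa (1,1), lambda (3,1), mu (1,2), nu (2,2)
        for s in range(100):
            scores = flow_scores(cat5, sample_index(cat5, seed=s))
            x3, x4 = scores["x3"], scores["x4"]
            assert 1 <= x3 <= 3 and 1 <= x4 <= 2 and x3 + x4 <= 4
            # affine position in the (kappa, lambda, mu) parametrisation
            w = corner_coordinates(
                scores, [corners[0], corners[1], corners[2]],
                require_convex=False,
            )
            assert sum(w, Fraction(0)) == 1
            p, q = w[1], w[2]
            assert 0 <= p <= 1 and 0 <= q <= 1 and p + q / 2 <= 1


class TestFamilyProperties:
    def test_fp_and_es_hold_both_properties(self):
        trees = [make_fixture(n) for n in ["cat5", "fig2", "fig3", "fig4a", "fig4b"]]
        trees += random_trees(15, n_min=3, n_max=8, multi=0.25)
        assert check_family_properties(fp_matrix, trees) == (True, True)
        assert check_family_properties(es_matrix, trees) == (True, True)

    def test_lambda_corner_family_breaks_monotonicity(self, cat5):
        from pdspace import class_key

        # lambda: keep edge h in the 3-leaf subtree, but send all of edge g
        # onto the single leaf x3 — the 2-leaf cherry receives 0 < 1
        lam_scheme = corner_scheme(
            cat5, {class_key(cat5, "h"): 0, class_key(cat5, "g"): 1}
        )
        family = lambda tree: ratios_to_matrix(tree, lam_scheme)
        prop1, prop2 = check_family_properties(family, [cat5])
        assert prop2 is False
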