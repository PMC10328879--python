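from fractions import Fraction

import pytest

from pdspace import make_fixture, random_tree


@pytest.fixture
def cat5():
    return make_fixture("cat5")


@pytest.fixture
def fig2():
    return make_fixture("fig2")


@pytest.fixture
def fig3():
    return make_fixture("fig3")


@pytest.fixture
def fig4a():
    return make_fixture("fig4a")


@pytest.fixture
def fig4b():
    return make_fixture("fig4b")


@pytest.fixture
def hominoid():
    return make_fixture("hominoid")


FIXTURE_SET = ["cat5", "fig2", "fig3", "fig4a", "fig4b", "hominoid", "cherry", "balanced8"]


@pytest.fixture(params=FIXTURE_SET)
def any_fixture(request):
    return make_fixture(request.param)


def random_trees(count, n_min=2, n_max=10, seed_base=0, multi=0.0, lengths=False):
    """Deterministic batch of random trees for property suites."""
    import random

    out = []
    for i in range(count):
        n = n_min + (i % (n_max - n_min + 1))
        sampler = None
        if lengths:
            # terminating-decimal rationals survive Newick text exactly
            sampler = lambda rng: Fraction(
                rng.randint(1, 40), rng.choice([1, 2, 4, 5, 8, 10, 16, 20])
            )
        out.append(
            random_tree(n, seed=seed_base + i, multifurcation_prob=multi,
                        length_sampler=sampler)
        )
    return out
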