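import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parsimorph import (
    MISSING,
    CharacterMatrix,
    CharacterMeta,
    char_lengths,
    max_steps,
    min_steps,
    mpr_states,
    parse_newick,
    random_topology,
    tree_length,
)
from conftest import all_topologies, brute_force_length, random_matrix

F = frozenset


def col(m, j=0):
    return m.column(j)


def test_quartet_lengths(quartet, quartet_matrix):
    assert char_lengths(quartet_matrix, quartet).tolist() == [1]
    other = parse_newick("((A,C),(B,D));")
    assert char_lengths(quartet_matrix, other).tolist() == [2]


def test_two_leaf_ordered_vs_unordered():
    t = parse_newick("(A,B);")
    mo = CharacterMatrix(["A", "B"], [[{0}], [{2}]], [CharacterMeta(1, ordered=True)])
    mu = CharacterMatrix(["A", "B"], [[{0}], [{2}]])
    assert char_lengths(mo, t).tolist() == [2]
    assert char_lengths(mu, t).tolist() == [1]


def test_ambiguity_resolved_most_parsimoniously(quartet):
    m = CharacterMatrix(list("ABCD"), [[{0, 1}], [{1}], [{0}], [MISSING]])
    for t in all_topologies(list("ABCD")):
        assert char_lengths(m, t).tolist() == [1]


def test_polytomy_scored_as_soft():
    star = parse_newick("(A,B,C,D);")
    m = CharacterMatrix(list("ABCD"), [[{0}], [{0}], [{1}], [{1}]])
    assert char_lengths(m, star).tolist() == [2]


def test_rooting_invariance():
    rng = random.Random(11)
    taxa = [f"t{i}" for i in range(8)]
    m = random_matrix(rng, taxa, 6)
    t = random_topology(taxa, 5)
    base = char_lengths(m, t)
    for leaf in list(t.leaf_node_iter())[:4]:
        t2 = t.clone(depth=1)
        lf = next(x for x in t2.leaf_node_iter() if x.taxon.label == leaf.taxon.label)
        t2.reroot_at_edge(lf.edge, update_bipartitions=False)
        assert char_lengths(m, t2).tolist() == base.tolist()


def test_engine_matches_exhaustive_enumeration():
    """DP lengths equal brute-force minimization over all internal states."""
    rng = random.Random(42)
    for case in range(60):
        n = rng.randint(4, 7)
        k = rng.randint(2, 4)
        taxa = [f"t{i}" for i in range(n)]
        m = random_matrix(rng, taxa, 2, k, ordered_prob=0.3)
        t = random_topology(taxa, rng.randrange(2**31))
        got = char_lengths(m, t)
        want = [brute_force_length(m, t, j, k) for j in range(2)]
        assert got.tolist() == want


@pytest.mark.parametrize(
    "cells,ordered,expected",
    [
        ([F({0}), F({1}), F({2})], False, 2),
        ([F({0}), F({1}), F({0, 1})], False, 1),
        ([MISSING, MISSING], False, 0),
        ([F({0}), F({2})], True, 2),
        ([F({0, 2}), F({1})], True, 1),  # resolve {0,2} to 0 (or 2): span 1
    ],
)
def test_min_steps(cells, ordered, expected):
    assert min_steps(cells, ordered=ordered) == expected


def test_min_steps_matches_brute_force_over_topologies():
    rng = random.Random(3)
    taxa = [f"t{i}" for i in range(5)]
    topos = all_topologies(taxa)
    for case in range(15):
        m = random_matrix(rng, taxa, 1, 3, ambig_prob=0.3)
        want = min(brute_force_length(m, t, 0, 3) for t in topos)
        assert min_steps(m.column(0)) == want


@pytest.mark.parametrize(
    "cells,expected",
    [
        ([F({0})] * 2 + [F({1})] * 2, 2),
        ([F({0})] * 3 + [F({1})], 1),
        ([F({0}), F({0, 1})], 1),
        ([MISSING, F({2})], 0),
    ],
)
def test_max_steps(cells, expected):
    assert max_steps(cells) == expected


def test_max_steps_is_star_tree_maximum():
    rng = random.Random(8)
    taxa = [f"t{i}" for i in range(5)]
    topos = all_topologies(taxa)
    for case in range(15):
        m = random_matrix(rng, taxa, 1, 3, ambig_prob=0.2, missing_prob=0.2)
        worst = max(brute_force_length(m, t, 0, 3) for t in topos)
        g = max_steps(m.column(0))
        assert g >= worst  # star maximum dominates any resolved topology


def test_bound_sandwich_on_random_topologies():
    rng = random.Random(21)
    taxa = [f"t{i}" for i in range(7)]
    for case in range(20):
        m = random_matrix(rng, taxa, 4, 3, ambig_prob=0.15, missing_prob=0.15)
        t = random_topology(taxa, rng.randrange(2**31))
        sc = tree_length(m, t)
        assert (sc.m <= sc.s).all() and (sc.s <= sc.g).all()
        assert sc.S == sc.s.sum() and sc.M == sc.m.sum() and sc.G == sc.g.sum()


def test_tree_length_requires_exact_label_match(quartet):
    m = CharacterMatrix(list("ABC"), [[{0}], [{1}], [{0}]])
    with pytest.raises(ValueError, match="D"):
        tree_length(m, quartet)


def test_mpr_sets_match_optimal_assignment_enumeration():
    """MPR sets equal the states used across all optimal brute-force
    assignments at each internal node."""
    from itertools import product

    rng = random.Random(17)
    taxa = [f"t{i}" for i in range(6)]
    for case in range(10):
        k = 3
        m = random_matrix(rng, taxa, 1, k, ambig_prob=0.2, missing_prob=0.2)
        t = random_topology(taxa, rng.randrange(2**31))
        mpr = mpr_states(m, t, 1)
        internal = [n for n in t.postorder_node_iter() if not n.is_leaf()]
        cell_of = dict(zip(m.taxa, (row[0] for row in m.cells)))
        best = None
        used = {id(n): set() for n in internal}
        for assign in product(range(k), repeat=len(internal)):
            state = {id(n): s for n, s in zip(internal, assign)}
            total = 0
            for n in internal:
                for c in n.child_nodes():
                    if c.is_leaf():
                        cell = cell_of[c.taxon.label]
                        allowed = range(k) if cell is MISSING else sorted(cell)
                        total += min(int(s != state[id(n)]) for s in allowed)
                    else:
                        total += int(state[id(n)] != state[id(c)])
            if best is None or total < best:
                best = total
                used = {id(n): {state[id(n)]} for n in internal}
            elif total == best:
                for n in internal:
                    used[id(n)].add(state[id(n)])
        assert mpr.total == best
        for n in internal:
            assert mpr.of(n) == frozenset(used[id(n)]), "MPR set mismatch"


_cells = st.lists(
    st.one_of(
        st.none(),
        st.frozensets(st.integers(0, 4), min_size=1, max_size=3),
    ),
    min_size=2,
    max_size=12,
)


@settings(derandomize=True, max_examples=60)
@given(_cells)
def test_step_bounds_properties(column):
    """min_steps <= max_steps; both invariant to cell order; the ordered
    minimum never undercuts the unordered one."""
    mu = min_steps(column)
    mo = min_steps(column, ordered=True)
    g = max_steps(column)
    assert 0 <= mu <= mo
    assert mu <= g
    shuffled = list(column)
    random.Random(0).shuffle(shuffled)
    assert min_steps(shuffled) == mu and max_steps(shuffled) == g


@settings(derandomize=True, max_examples=25)
@given(st.integers(0, 10_000))
def test_random_topology_lengths_respect_bounds(seed):
    rng = random.Random(seed)
    taxa = [f"t{i}" for i in range(6)]
    m = random_matrix(rng, taxa, 3, 3, ambig_prob=0.2, missing_prob=0.2)
    t = random_topology(taxa, seed)
    sc = tree_length(m, t)
    assert (sc.m <= sc.s).all() and (sc.s <= sc.g).all()


def test_mpr_constant_column_single_state(quartet):
    m = CharacterMatrix(list("ABCD"), [[{2}], [{2}], [{2}], [MISSING]])
    mpr = mpr_states(m, quartet, 1)
    for node in quartet.postorder_node_iter():
        if not node.is_leaf():
            assert mpr.of(node) == frozenset({2})
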