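import random

import pytest

from parsimorph import (
    CharacterMatrix,
    SearchConfig,
    bipartitions,
    displays,
    drop_invariant_characters,
    ensemble_lengths,
    parse_newick,
    restrict_to,
    rf_distance,
    search,
    strict_consensus,
    tree_length,
)
from parsimorph.search import collapse_zero_length_branches
from parsimorph.simulate import SimulationConfig, sim_tree, simulate_matrix
from conftest import all_topologies, random_matrix


def test_homoplasy_free_matrix_recovers_generating_tree():
    true = sim_tree(6, seed=31)
    m, _ = simulate_matrix(
        SimulationConfig(tree=true, n_chars=40, mode="homoplasy_free", seed=37)
    )
    res = search(m, SearchConfig(n_replicates=3, seed=41))
    assert res.best_score == tree_length(m, true).M
    assert len(res.trees) == 1
    assert rf_distance(res.trees[0], true) == 0


def test_search_matches_exhaustive_minimum_small_n():
    rng = random.Random(101)
    for case in range(8):
        n = rng.randint(5, 6)
        taxa = [f"t{i}" for i in range(n)]
        m = random_matrix(rng, taxa, 10, 3, ambig_prob=0.1, missing_prob=0.1)
        best_exhaustive = min(
            int(x) for x in ensemble_lengths(m, all_topologies(taxa))
        )
        res = search(m, SearchConfig(n_replicates=3, seed=rng.randrange(2**31)))
        assert res.best_score == best_exhaustive


def test_constraint_is_displayed_by_every_result():
    true = sim_tree(8, seed=9)
    m, _ = simulate_matrix(
        SimulationConfig(tree=true, n_chars=50, mode="mk", rate=0.4, seed=10)
    )
    m, _ = drop_invariant_characters(m)
    backbone = restrict_to(true, ["t1", "t2", "t3", "t4", "t5"])
    res = search(m, SearchConfig(n_replicates=2, seed=11, constraint=backbone))
    for t in res.trees:
        assert displays(t, backbone)
        assert rf_distance(restrict_to(t, ["t1", "t2", "t3", "t4", "t5"]), backbone) == 0


def test_implied_weights_prefers_fewer_extra_steps():
    true = sim_tree(6, seed=5)
    m, _ = simulate_matrix(
        SimulationConfig(tree=true, n_chars=40, mode="homoplasy_free", seed=6)
    )
    res = search(m, SearchConfig(criterion="implied", k=12, n_replicates=2, seed=7))
    assert res.best_score == 0.0  # no extra steps on the true tree
    assert rf_distance(res.trees[0], true) == 0


def test_seeded_determinism_and_replicate_monotonicity():
    rng = random.Random(55)
    taxa = [f"t{i}" for i in range(7)]
    m = random_matrix(rng, taxa, 12, 3)
    a = search(m, SearchConfig(n_replicates=3, seed=2))
    b = search(m, SearchConfig(n_replicates=3, seed=2))
    assert a.best_score == b.best_score
    assert {bipartitions(t) for t in a.trees} == {bipartitions(t) for t in b.trees}
    more = search(m, SearchConfig(n_replicates=6, seed=2))
    assert more.best_score <= a.best_score


def test_nni_swap_supported():
    true = sim_tree(6, seed=13)
    m, _ = simulate_matrix(
        SimulationConfig(tree=true, n_chars=30, mode="homoplasy_free", seed=14)
    )
    res = search(m, SearchConfig(n_replicates=4, swap="NNI", seed=15))
    assert res.best_score == tree_length(m, true).M


def test_strict_consensus_cases():
    t = parse_newick("(((A,B),C),(D,E));")
    assert bipartitions(strict_consensus([t])) == bipartitions(t)
    quartets = [
        parse_newick("((A,B),(C,D));"),
        parse_newick("((A,C),(B,D));"),
        parse_newick("((A,D),(B,C));"),
    ]
    assert bipartitions(strict_consensus(quartets)) == frozenset()
    # two 6-leaf trees sharing exactly one internal split
    a = parse_newick("(((A,B),C),((D,E),F));")
    b = parse_newick("(((A,B),D),((C,E),F));")
    shared = bipartitions(a) & bipartitions(b)
    cons = bipartitions(strict_consensus([a, b]))
    assert cons == shared and len(cons) >= 1
    with pytest.raises(ValueError):
        strict_consensus([t, parse_newick("((A,B),(C,F));")])


def test_collapse_zero_length_branches():
    m = CharacterMatrix(list("ABCDEF"), [[{0}], [{0}], [{0}], [{1}], [{1}], [{1}]])
    t = parse_newick("(((A,B),C),((D,E),F));")
    out = collapse_zero_length_branches(m, t)
    assert bipartitions(out) == frozenset({frozenset({"D", "E", "F"})})
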