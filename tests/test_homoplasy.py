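import random
from collections import Counter

import numpy as np
import pytest

from parsimorph import (
    MISSING,
    CharacterMatrix,
    char_lengths,
    drop_invariant_characters,
    ensemble_indices,
    implied_weights_fit,
    parse_newick,
    permute_within_characters,
    random_topology,
    rhi,
    tree_length,
)
from parsimorph.homoplasy import null_length_sample
from parsimorph.parsimony import StepCounts, max_steps, min_steps
from parsimorph.simulate import SimulationConfig, sim_tree, simulate_matrix
from conftest import random_matrix


def test_ci_arithmetic():
    sc = StepCounts([1, 2], np.array([2, 2]), np.array([1, 1]), np.array([3, 3]))
    ci, ri = ensemble_indices(sc)
    assert ci == pytest.approx(0.5)
    assert ri == pytest.approx((6 - 4) / (6 - 2))


def test_single_character_worst_quartet():
    m = CharacterMatrix(list("ABCD"), [[{0}], [{1}], [{0}], [{1}]])
    t = parse_newick("((A,B),(C,D));")  # 0,1 vs 0,1: two steps required
    sc = tree_length(m, t)
    assert (sc.s[0], sc.m[0], sc.g[0]) == (2, 1, 2)
    ci, ri = ensemble_indices(sc)
    assert ci == pytest.approx(0.5) and ri == pytest.approx(0.0)


def test_errors_on_degenerate_sums():
    sc = StepCounts([1], np.array([0]), np.array([0]), np.array([0]))
    with pytest.raises(ValueError):
        ensemble_indices(sc)


def test_homoplasy_free_matrix_has_ci_ri_one_rhi_zero():
    t = sim_tree(10, seed=3)
    m, _ = simulate_matrix(
        SimulationConfig(tree=t, n_chars=40, mode="homoplasy_free", seed=5)
    )
    res = rhi(m, t, null_n=60, seed=9)
    assert res.ci == 1.0 and res.ri == 1.0
    assert res.rhi == 0.0 and res.rhi_lo == 0.0 and res.rhi_hi == 0.0


def test_rhi_seeded_null_stream_replays():
    """The null sample is exactly reproducible from the seed by replaying
    the documented sub-seed stream through the topology sampler."""
    t = sim_tree(7, seed=1)
    m, _ = simulate_matrix(SimulationConfig(tree=t, n_chars=25, mode="mk", rate=0.8, seed=2))
    m, _ = drop_invariant_characters(m)
    D = null_length_sample(m, 30, seed=12345)
    rng = random.Random(12345)
    replay = [
        int(char_lengths(m, random_topology(m.taxa, rng.randrange(2**31)),
                         treat_unordered=True).sum())
        for _ in range(30)
    ]
    assert D.tolist() == replay
    res = rhi(m, t, null_n=30, seed=12345)
    S, M = res.L, res.M
    assert res.rhi == pytest.approx((S - M) / (np.median(replay) - M))


def test_rhi_monotone_in_tree_quality():
    """Scoring the same matrix on a worse topology (larger S) raises RHI."""
    t = sim_tree(10, seed=21)
    m, _ = simulate_matrix(SimulationConfig(tree=t, n_chars=60, mode="mk", rate=0.4, seed=22))
    m, _ = drop_invariant_characters(m)
    good = rhi(m, t, null_n=80, seed=1)
    bad_tree = random_topology(m.taxa, 999)
    bad = rhi(m, bad_tree, null_n=80, seed=1)
    if tree_length(m, bad_tree, treat_unordered=True).S > good.L:
        assert bad.rhi > good.rhi


def test_permutation_preserves_column_multisets_and_bounds():
    rng = random.Random(5)
    taxa = [f"t{i}" for i in range(9)]
    m = random_matrix(rng, taxa, 12, ambig_prob=0.2, missing_prob=0.2)
    p = permute_within_characters(m, seed=77)
    for j in range(m.n_char):
        assert Counter(map(repr, m.column(j))) == Counter(map(repr, p.column(j)))
        assert min_steps(m.column(j)) == min_steps(p.column(j))
        assert max_steps(m.column(j)) == max_steps(p.column(j))
    assert permute_within_characters(m, seed=77) == p  # deterministic


def test_permutation_with_fixed_missing_pattern():
    m = CharacterMatrix(
        list("ABCD"), [[{0}], [MISSING], [{1}], [MISSING]]
    )
    p = permute_within_characters(m, seed=3, keep_missing_fixed=True)
    assert [c is MISSING for c in p.column(0)] == [False, True, False, True]


def test_permuted_matrix_rhi_interval_covers_one():
    t = sim_tree(14, seed=8)
    m, _ = simulate_matrix(
        SimulationConfig(tree=t, n_chars=150, mode="mk", rate=0.5, seed=4)
    )
    perm = permute_within_characters(m, seed=6)
    perm, _ = drop_invariant_characters(perm)
    res = rhi(perm, t, null_n=150, seed=10)
    assert res.rhi_lo <= 1.02 and res.rhi_hi >= 0.98
    assert res.rhi == pytest.approx(1.0, abs=0.1)


def test_indices_invariant_to_taxon_and_character_order():
    rng = random.Random(31)
    taxa = [f"t{i}" for i in range(7)]
    m = random_matrix(rng, taxa, 8, ambig_prob=0.1)
    t = random_topology(taxa, 3)
    base = rhi(m, t, null_n=40, seed=2)
    # permute taxa rows and character columns
    perm_t = list(taxa)
    rng.shuffle(perm_t)
    perm_c = list(range(8))
    rng.shuffle(perm_c)
    rows = [[m.row(tx)[j] for j in perm_c] for tx in perm_t]
    m2 = CharacterMatrix(perm_t, rows)
    out = rhi(m2, t, null_n=40, seed=2)
    assert (out.ci, out.ri) == (base.ci, base.ri)
    assert out.L == base.L and out.M == base.M and out.G == base.G


def test_implied_weights_fit():
    sc = StepCounts([1, 2], np.array([12, 3]), np.array([0, 3]), np.array([20, 5]))
    fit = implied_weights_fit(sc, k=12)
    assert fit.f.tolist() == [0.5, 0.0]
    assert fit.F == pytest.approx(0.5)
    with pytest.raises(ValueError):
        implied_weights_fit(sc, k=0)


def test_implied_weights_monotone_in_extra_steps():
    base = StepCounts([1, 2], np.array([5, 4]), np.array([1, 1]), np.array([9, 9]))
    better = StepCounts([1, 2], np.array([4, 4]), np.array([1, 1]), np.array([9, 9]))
    assert implied_weights_fit(better).F < implied_weights_fit(base).F
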