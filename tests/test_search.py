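"""Tree search: stepwise addition, TBR local optimality, exact search."""

import numpy as np
import pytest

from morphoclad.matrix import CharacterMatrix
from morphoclad.search import (
    SearchConfig,
    SearchError,
    branch_and_bound,
    collapse_zero_length,
    heuristic_search,
    stepwise_addition,
)

from conftest import all_topologies, brute_force_length, random_matrix, tbr_neighbors


def exhaustive_best(matrix, weights=None):
    """Optimal length and all optimal topologies by full enumeration."""
    best, trees = None, []
    for t in all_topologies(matrix.taxa):
        L = brute_force_length(t, matrix, weights)
        if best is None or L < best - 1e-9:
            best, trees = L, [t]
        elif abs(L - best) <= 1e-9:
            trees.append(t)
    return best, trees


def test_branch_and_bound_equals_enumeration():
    for seed in range(5):
        _, m = random_matrix(seed, n_taxa=6, n_char=7, p=0.3)
        best, trees = exhaustive_best(m)
        res = branch_and_bound(m)
        assert res.best_length == pytest.approx(best)
        assert {t.canonical_newick for t in res.binary_trees} == {
            t.canonical_newick for t in trees
        }


def test_bound_prunes_but_preserves_optimum():
    _, m = random_matrix(9, n_taxa=7, n_char=8, p=0.3)
    full = branch_and_bound(m, use_bound=False)
    pruned = branch_and_bound(m, use_bound=True)
    assert full.n_visited == len(all_topologies(m.taxa))  # 945 for 7 taxa
    assert pruned.n_visited < full.n_visited
    assert pruned.best_length == full.best_length
    assert {t.canonical_newick for t in pruned.binary_trees} == {
        t.canonical_newick for t in full.binary_trees
    }


def test_heuristic_matches_exact():
    for seed in range(6):
        _, m = random_matrix(100 + seed, n_taxa=8, n_char=8, p=0.3, three_state=(1,))
        exact = branch_and_bound(m)
        heur = heuristic_search(m, config=SearchConfig(n_replicates=5, seed=seed))
        assert heur.best_length == pytest.approx(exact.best_length)
        assert {t.canonical_newick for t in heur.binary_trees} == {
            t.canonical_newick for t in exact.binary_trees
        }


def test_result_is_tbr_local_optimum():
    _, m = random_matrix(42, n_taxa=8, n_char=10, p=0.35)
    res = heuristic_search(m, config=SearchConfig(n_replicates=3, seed=0))
    tree = res.binary_trees[0]
    base = brute_force_length(tree, m)
    assert base == pytest.approx(res.best_length)
    # no TBR rearrangement (independent oracle) improves the result
    for nb in tbr_neighbors(tree):
        assert brute_force_length(nb, m) >= base - 1e-9


def test_stepwise_addition_deterministic():
    _, m = random_matrix(7, n_taxa=7, n_char=6, p=0.3)
    t1 = stepwise_addition(m, order=list(range(7)), hold=1)
    t2 = stepwise_addition(m, order=list(range(7)), hold=1)
    assert len(t1) == 1
    assert t1[0].canonical_newick == t2[0].canonical_newick
    held = stepwise_addition(m, order=list(range(7)), hold=5)
    assert 1 <= len(held) <= 5
    # lengths are sorted: the first held tree is at least as short
    assert brute_force_length(held[0], m) <= brute_force_length(held[-1], m) + 1e-9


def test_beam_start_never_worse_than_greedy():
    for seed in (3, 4):
        _, m = random_matrix(200 + seed, n_taxa=8, n_char=8, p=0.35)
        order = list(np.random.default_rng(seed).permutation(8))
        g = stepwise_addition(m, order=order, hold=1)[0]
        b = stepwise_addition(m, order=order, hold=8)[0]
        assert brute_force_length(b, m) <= brute_force_length(g, m) + 1e-9


def test_weighted_search_respects_weights():
    # two conflicting binary characters; the heavier one must win
    data = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    m = CharacterMatrix(list("ABCD"), data)
    w = np.array([1.0, 10.0])
    res = branch_and_bound(m, weights=w)
    assert res.best_length == pytest.approx(12.0)  # char 2 clean (10), char 1 twice
    assert frozenset({"B", "D"}) in res.binary_trees[0].bipartitions


def test_zero_length_collapse_reports_polytomy():
    # B autapomorphic-only: the internal edge attaching it is unsupported
    data = np.array([[0, 0], [0, 0], [1, 1], [1, 1], [0, 0]])
    m = CharacterMatrix(list("ABCDE"), data)
    res = branch_and_bound(m)
    # every binary resolution collapses to the single supported split C|D
    for t in res.binary_trees:
        assert collapse_zero_length(t, m).bipartitions == {frozenset({"C", "D"})}
    assert len(res.trees) == 1
    assert res.trees[0].bipartitions == {frozenset({"C", "D"})}


def test_replicate_log_and_config_validation():
    _, m = random_matrix(1, n_taxa=6, n_char=5, p=0.3)
    res = heuristic_search(m, config=SearchConfig(n_replicates=4, seed=1))
    assert len(res.replicate_log) == 4
    assert min(res.replicate_log) == pytest.approx(res.best_length)
    assert list(res.log_table()["best_length"]) == res.replicate_log
    with pytest.raises(SearchError):
        SearchConfig(n_replicates=0)
    with pytest.raises(SearchError):
        SearchConfig(swap="spr")
    with pytest.raises(SearchError):
        branch_and_bound(random_matrix(0, n_taxa=13, n_char=4)[1])


def test_search_reproducible():
    _, m = random_matrix(77, n_taxa=9, n_char=9, p=0.3)
    r1 = heuristic_search(m, config=SearchConfig(n_replicates=5, seed=9))
    r2 = heuristic_search(m, config=SearchConfig(n_replicates=5, seed=9))
    assert r1.best_length == r2.best_length
    assert [t.canonical_newick for t in r1.binary_trees] == [
        t.canonical_newick for t in r2.binary_trees
    ]
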