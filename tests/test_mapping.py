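"""Ancestral-state mapping: MPR enumeration, unambiguous changes, classes."""

import itertools

import numpy as np
import pytest

from morphoclad.mapping import (
    MappingError,
    annotated_newick,
    map_characters,
    enumerate_mprs,
    unambiguous_changes,
)
from morphoclad.matrix import MISSING, CharacterMatrix
from morphoclad.parsimony import per_character_steps
from morphoclad.simulate import SimConfig, evolve_matrix, sample_topology
from morphoclad.trees import Tree

from conftest import random_matrix


def rooted_quartet():
    t = Tree(list("ABCD"), [[4], [4], [5], [5], [0, 1, 5], [2, 3, 4]])
    return t, t.root_on_edge(4, 0)  # root on A's pendant edge


def brute_force_mprs(rtree, matrix, char):
    """All minimum-cost internal-node assignments by exhaustive enumeration
    (missing leaves cost nothing on their pendant edge)."""
    obs = matrix.char_meta[char].observed_states or (0,)
    internal = [n for n in range(rtree.n_nodes) if not rtree.is_leaf(n)]
    best, out = None, []
    for combo in itertools.product(obs, repeat=len(internal)):
        assign = dict(zip(internal, combo))
        for i, t in enumerate(rtree.taxa):
            s = matrix.cell(t, char)
            assign[i] = None if s == MISSING else s
        cost = sum(
            1
            for node in range(rtree.n_nodes)
            if node != rtree.root
            and assign[node] is not None
            and assign[node] != assign[rtree.parent[node]]
        )
        if best is None or cost < best:
            best, out = cost, [dict(assign)]
        elif cost == best:
            out.append(dict(assign))
    return best, [{n: a[n] for n in internal} for a in out]


def internal_only(rtree, assignments):
    """Project full node->state MPRs onto internal nodes, deduplicated."""
    internal = [n for n in range(rtree.n_nodes) if not rtree.is_leaf(n)]
    return {tuple(sorted((n, a[n]) for n in internal)) for a in assignments}


def test_quartet_single_mpr():
    _, r = rooted_quartet()
    m = CharacterMatrix(list("ABCD"), np.array([[0], [0], [1], [1]]))
    mprs = enumerate_mprs(r, m, 0)
    assert mprs.n_mprs == 1 and mprs.min_length == 1
    assert mprs.acctran == mprs.deltran == mprs.assignments[0]
    changes = unambiguous_changes(r, m)
    assert len(changes) == 1
    ch = changes[0]
    assert (ch.from_state, ch.to_state) == (0, 1)
    # the change sits on the stem of the (C, D) clade
    assert r.leafset[ch.branch] == frozenset({2, 3})


def test_pectinate_alternating_has_ambiguous_changes():
    # (D,(C,(A,B))) with states 0,1,0,1: >= 2 MPRs, nothing unambiguous
    t = Tree(list("ABCD"), [[4], [4], [5], [5], [0, 1, 5], [2, 3, 4]])
    r = t.root_on_edge(t.neighbors(3)[0], 3)
    m = CharacterMatrix(list("ABCD"), np.array([[0], [1], [0], [1]]))
    mprs = enumerate_mprs(r, m, 0)
    assert mprs.min_length == 2
    assert internal_only(r, mprs.assignments) >= {
        tuple(sorted(a.items())) for a in brute_force_mprs(r, m, 0)[1][:1]
    }
    assert len(internal_only(r, mprs.assignments)) >= 2
    assert unambiguous_changes(r, m) == []


def test_invariant_character_single_changeless_mpr():
    _, r = rooted_quartet()
    m = CharacterMatrix(list("ABCD"), np.array([[0, 0], [0, 1], [0, 0], [0, 1]]))
    mprs = enumerate_mprs(r, m, 0)
    assert mprs.n_mprs == 1 and mprs.min_length == 0
    assert set(mprs.assignments[0].values()) == {0}


@pytest.mark.parametrize("seed", range(8))
def test_mpr_set_matches_brute_force(seed):
    tree, m = random_matrix(300 + seed, n_taxa=6, n_char=5, p=0.35, three_state=(1,))
    r = tree.root_on_edge(tree.neighbors(0)[0], 0)
    for c in range(m.n_char):
        best, assigns = brute_force_mprs(r, m, c)
        mprs = enumerate_mprs(r, m, c)
        assert mprs.min_length == best
        expected = {tuple(sorted(a.items())) for a in assigns}
        assert internal_only(r, mprs.assignments) == expected
        assert internal_only(r, [mprs.acctran]) <= expected
        assert internal_only(r, [mprs.deltran]) <= expected


@pytest.mark.parametrize("seed", range(6))
def test_unambiguous_iff_identical_across_all_mprs(seed):
    tree, m = random_matrix(400 + seed, n_taxa=7, n_char=6, p=0.3)
    r = tree.root_on_edge(tree.neighbors(0)[0], 0)
    got = {(c.char, c.branch, c.from_state, c.to_state) for c in unambiguous_changes(r, m)}
    expected = set()
    for c in range(m.n_char):
        _, assigns = brute_force_mprs(r, m, c)
        full = []
        for a in assigns:
            d = dict(a)
            for i, t in enumerate(r.taxa):
                s = m.cell(t, c)
                d[i] = None if s == MISSING else s
            full.append(d)
        for node in range(r.n_nodes):
            if node == r.root or full[0][node] is None:
                continue
            pairs = {(d[r.parent[node]], d[node]) for d in full}
            if len(pairs) == 1:
                fs, ts = next(iter(pairs))
                if fs != ts:
                    expected.add((c, node, fs, ts))
    assert got == expected


def test_mpr_changes_sum_to_fitch_length():
    tree, m = random_matrix(55, n_taxa=8, n_char=6, p=0.35)
    r = tree.root_on_edge(tree.neighbors(0)[0], 0)
    steps = per_character_steps(tree, m)
    for c in range(m.n_char):
        mprs = enumerate_mprs(r, m, c)
        for a in mprs.assignments:
            n_changes = sum(
                1
                for node in range(r.n_nodes)
                if node != r.root and a[node] != a[r.parent[node]]
            )
            assert n_changes == mprs.min_length == steps[c]


def caterpillar_tree():
    """((((((A,B),C),D),E),F), (G,(H,I))) as an unrooted tree; rooted on
    the central edge (n13, n14), so the (A..E) clade stem is NOT adjacent
    to the root (a lone root-adjacent change could slide across the root
    and become ambiguous)."""
    taxa = list("ABCDEFGHI")
    nbrs = [
        [9], [9], [10], [11], [12], [13],  # A..F
        [14], [15], [15],  # G H I
        [0, 1, 10],     # n9  = (A,B)
        [2, 9, 11],     # n10 = (n9, C)
        [3, 10, 12],    # n11 = (n10, D)
        [4, 11, 13],    # n12 = (n11, E)
        [5, 12, 14],    # n13 = (n12, F)
        [6, 13, 15],    # n14 = (G, n15)
        [7, 8, 14],     # n15 = (H,I)
    ]
    t = Tree(taxa, nbrs)
    return t, t.root_on_edge(13, 14)


def test_classification_parallelism():
    t, r = caterpillar_tree()
    # state 1 fixed in clades (A,B) and (H,I): two independent origins
    data = np.array([[1], [1], [0], [0], [0], [0], [0], [1], [1]])
    m = CharacterMatrix(t.taxa, data)
    summary = map_characters(r, m)
    classes = [c.homoplasy_class for c in summary.changes]
    assert classes == ["parallelism", "parallelism"]
    assert {r.leafset[c.branch] for c in summary.changes} == {
        frozenset({0, 1}), frozenset({7, 8})
    }
    assert summary.totals["parallelism"] == 2


def test_classification_reversal_pair():
    t, r = caterpillar_tree()
    # state 1 gained on the (A..E) stem and lost again on the (A,B) stem:
    # the unique MPR (gain+loss = 2 < three independent gains) yields one
    # loss classed reversal and one origin that reverts (also "reversal")
    data = np.array([[0], [0], [1], [1], [1], [0], [0], [0], [0]])
    m = CharacterMatrix(t.taxa, data)
    summary = map_characters(r, m)
    by_dir = {(c.from_state, c.to_state): c.homoplasy_class for c in summary.changes}
    assert len(summary.changes) == 2
    assert by_dir[(1, 0)] == "reversal"
    assert by_dir[(0, 1)] == "reversal"
    assert summary.totals["reversal"] == 2
    assert summary.characters_with("reversal") == [1]


def test_apomorphy_on_clean_clade_character():
    _, r = rooted_quartet()
    m = CharacterMatrix(list("ABCD"), np.array([[0], [0], [1], [1]]))
    summary = map_characters(r, m)
    assert summary.totals == {
        "apomorphy": 1, "parallelism": 0, "reversal": 0, "parallel-reversal": 0
    }


def test_multistate_ladder_keeps_apomorphy():
    t, r = caterpillar_tree()
    # 0 -> 1 on the (A..E) stem, then 1 -> 2 on the (A,B) stem: the second
    # change goes to a new state, so the first stays an apomorphy
    data = np.array([[2], [2], [1], [1], [1], [0], [0], [0], [0]])
    m = CharacterMatrix(t.taxa, data)
    summary = map_characters(r, m)
    by_dir = {(c.from_state, c.to_state): c.homoplasy_class for c in summary.changes}
    assert by_dir[(0, 1)] == "apomorphy"
    assert by_dir[(1, 2)] == "apomorphy"


def test_outgroup_changes_unclassified():
    taxa = ["sp1", "sp2", "sp3", "og1", "og2"]
    t = Tree(
        taxa,
        [[5], [5], [6], [7], [7], [0, 1, 6], [2, 5, 7], [3, 4, 6]],
    )
    # og1 alone has the derived state: the unique MPR puts the change on
    # og1's pendant branch, inside the outgroup subtree
    m = CharacterMatrix(
        taxa, np.array([[0], [0], [0], [1], [0]]), outgroup_taxa=("og1", "og2")
    )
    r = t.root_with_outgroups(m.outgroup_taxa)
    summary = map_characters(r, m)
    assert len(summary.changes) == 1
    rec = summary.changes[0]
    assert rec.in_outgroup and rec.homoplasy_class is None
    assert summary.per_char == {}  # nothing classified on the ingroup side


def test_missing_leaf_branch_never_unambiguous():
    _, r = rooted_quartet()
    m = CharacterMatrix(list("ABCD"), np.array([[0], [0], [MISSING], [1]]))
    for ch in unambiguous_changes(r, m):
        assert r.leafset[ch.branch] != frozenset({2})  # not C's pendant branch


def test_unrooted_tree_refused(quartet_matrix):
    t = Tree(list("ABCD"), [[4], [4], [5], [5], [0, 1, 5], [2, 3, 4]])
    with pytest.raises(MappingError, match="rooted"):
        unambiguous_changes(t, quartet_matrix)


def test_annotated_newick_contains_change_strings():
    _, r = rooted_quartet()
    m = CharacterMatrix(list("ABCD"), np.array([[0], [0], [1], [1]]))
    text = annotated_newick(r, m)
    assert "[1:0>1]" in text


def test_low_homoplasy_recovery_against_change_log():
    # every logged change of a once-changing character on an informative
    # clade must be recovered exactly (root-adjacent branches are excluded:
    # a lone change there can always slide across the root)
    tree = sample_topology(9, seed=6)
    cfg = SimConfig(n_taxa=9, n_char=40, p=0.02, seed=12)
    m = evolve_matrix(tree, cfg)
    r = tree.root_on_edge(tree.neighbors(0)[0], 0)
    got = {
        (frozenset(r.taxa[i] for i in r.leafset[c.branch]), c.char, c.from_state, c.to_state)
        for c in unambiguous_changes(r, m)
    }
    per_char_counts = {}
    for e in m.change_log:
        per_char_counts[e["char"]] = per_char_counts.get(e["char"], 0) + 1
    checked = 0
    for e in m.change_log:
        if per_char_counts[e["char"]] == 1 and 2 <= len(e["clade"]) <= 7:
            assert (e["clade"], e["char"], e["from"], e["to"]) in got
            checked += 1
    assert checked >= 3  # the fixed seed produces enough informative singles
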