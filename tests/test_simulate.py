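"""The synthetic-data generator: topology sampling, change logs, preset shape."""

import numpy as np
import pytest

from morphoclad.matrix import MISSING
from morphoclad.simulate import (
    ENDOPHALLUS_CHARS,
    FEMALE_CHARS,
    N_ENDOPHALLUS_UNKNOWN,
    N_FEMALE_UNKNOWN,
    PAPERLIKE_N_CHAR,
    PAPERLIKE_THREE_STATE,
    SimConfig,
    SimulationError,
    evolve_matrix,
    make_paperlike,
    sample_topology,
    partition_from_tree,
)


def test_sample_topology_is_binary_and_seeded():
    t1 = sample_topology(8, seed=5)
    t2 = sample_topology(8, seed=5)
    t3 = sample_topology(8, seed=6)
    assert t1.is_binary and t1.n_leaves == 8
    assert t1.same_topology(t2)
    assert t1.canonical_newick == t2.canonical_newick
    assert not t3.same_topology(t1)  # overwhelmingly likely; fixed seeds


def test_sample_topology_covers_all_quartets():
    # with 4 taxa there are exactly 3 topologies; uniform sampling hits all
    seen = {sample_topology(4, seed=s).canonical_newick for s in range(60)}
    assert len(seen) == 3


def test_change_log_replays_to_matrix():
    tree = sample_topology(10, seed=1)
    cfg = SimConfig(n_taxa=10, n_char=30, p=0.1, seed=7)
    m = evolve_matrix(tree, cfg)
    # replay: start everything at 0 and apply the logged changes; clades in
    # the log are nested or disjoint, so applying large-to-small is valid
    state = {(t, c): 0 for t in m.taxa for c in range(m.n_char)}
    for entry in sorted(m.change_log, key=lambda e: -len(e["clade"])):
        for t in entry["clade"]:
            assert state[(t, entry["char"])] == entry["from"]
            state[(t, entry["char"])] = entry["to"]
    for i, t in enumerate(m.taxa):
        for c in range(m.n_char):
            assert state[(t, c)] == m.data[i, c]


def test_zero_rate_gives_invariant_matrix():
    tree = sample_topology(6, seed=0)
    m = evolve_matrix(tree, SimConfig(n_taxa=6, n_char=5, p=0.0, seed=0))
    assert not m.change_log
    assert (np.asarray(m.data) == 0).all()


def test_ensure_variable_redraws_invariant_characters():
    tree = sample_topology(8, seed=2)
    cfg = SimConfig(n_taxa=8, n_char=40, p=0.02, ensure_variable=True, seed=9)
    m = evolve_matrix(tree, cfg)
    for c in range(m.n_char):
        assert len(m.char_meta[c].observed_states) >= 2
    # the change log still replays to the matrix
    state = {(t, c): 0 for t in m.taxa for c in range(m.n_char)}
    for entry in sorted(m.change_log, key=lambda e: -len(e["clade"])):
        for t in entry["clade"]:
            state[(t, entry["char"])] = entry["to"]
    for i, t in enumerate(m.taxa):
        for c in range(m.n_char):
            assert state[(t, c)] == m.data[i, c]


def test_missing_blocks_applied():
    tree = sample_topology(6, seed=0)
    cfg = SimConfig(
        n_taxa=6, n_char=5, p=0.2, missing_blocks=(((0, 2), (1, 3)),), seed=3
    )
    m = evolve_matrix(tree, cfg)
    for t in (0, 2):
        for c in (1, 3):
            assert m.data[t, c] == MISSING


def test_config_validation():
    with pytest.raises(SimulationError):
        SimConfig(n_taxa=5, n_char=3, p=1.5)
    with pytest.raises(SimulationError):
        SimConfig(n_taxa=5, n_char=3, state_counts=(2, 2))
    with pytest.raises(SimulationError):
        sample_topology(3)


def test_paperlike_shape(paperlike):
    tree, m = paperlike
    assert m.n_taxa == 25 and m.n_char == PAPERLIKE_N_CHAR
    assert m.outgroup_taxa == ("out1", "out2")
    assert tree.is_binary
    # outgroups form a cherry (rootable split)
    og_ids = {m.taxa.index(t) for t in m.outgroup_taxa}
    assert any(tree.leaves_behind(u, v) == frozenset(og_ids) for u, v in tree.edges())
    # three-state characters show all three states; everything variable
    for c in range(m.n_char):
        k = len(m.char_meta[c].observed_states)
        assert k == (3 if c in PAPERLIKE_THREE_STATE else 2)
    # missing blocks have the study's row/column shape
    miss = np.asarray(m.data) == MISSING
    endo_rows = {i for i in range(25) if miss[i][list(ENDOPHALLUS_CHARS)].all()}
    fem_rows = {i for i in range(25) if miss[i][list(FEMALE_CHARS)].all()}
    assert len(endo_rows) == N_ENDOPHALLUS_UNKNOWN
    assert len(fem_rows) == N_FEMALE_UNKNOWN
    assert miss.sum() == (
        N_ENDOPHALLUS_UNKNOWN * len(ENDOPHALLUS_CHARS)
        + N_FEMALE_UNKNOWN * len(FEMALE_CHARS)
    )


def test_paperlike_reproducible():
    t1, m1 = make_paperlike(seed=42)
    t2, m2 = make_paperlike(seed=42)
    assert m1 == m2
    assert t1.same_topology(t2)


def test_partition_from_tree_covers_ingroup(paperlike):
    tree, m = paperlike
    part = partition_from_tree(tree, m, n_groups=4)
    assert len(part.groups) == 4
    part.validate_against(m)  # exact disjoint cover of the ingroup
    rooted = tree.root_with_outgroups(m.outgroup_taxa)
    from morphoclad.groups import test_monophyly

    for members in part.groups.values():
        ok, intruders = test_monophyly(rooted, members)
        assert ok and not intruders  # groups are clades of the truth tree
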