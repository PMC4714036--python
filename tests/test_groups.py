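"""Group diagnosis against a literal restatement of the three definitions."""

import numpy as np
import pytest

from morphoclad.groups import DiagnosisTable, GroupError, GroupPartition, diagnose_groups
from morphoclad.groups import test_monophyly as monophyly  # avoid test collection
from morphoclad.matrix import MISSING, CharacterMatrix
from morphoclad.simulate import sample_topology
from morphoclad.trees import Tree


def literal_diagnosis(matrix, partition):
    """Brute-force transcription of the definitive/exclusive/common rules."""
    out = {"definitive": {}, "exclusive": {}, "common": {}}
    ingroup = matrix.ingroup_taxa
    for name in partition.groups:
        for label in out:
            out[label][name] = []
    for c in range(matrix.n_char):
        for y in matrix.char_meta[c].observed_states:
            if y == 0:
                continue
            scored = [t for t in ingroup if matrix.cell(t, c) != MISSING]
            has = [t for t in scored if matrix.cell(t, c) == y]
            if scored and len(has) == len(scored):
                continue  # fixed subgenus-wide: undiagnostic
            for name, members in partition.groups.items():
                g_scored = [t for t in scored if t in members]
                if not g_scored:
                    continue
                all_in = all(t in has for t in g_scored)
                some_in = any(t in has for t in g_scored)
                none_out = all(t in members for t in has)
                pair = (c + 1, int(y))
                if all_in and none_out:
                    out["definitive"][name].append(pair)
                elif some_in and not all_in and none_out:
                    out["exclusive"][name].append(pair)
                elif all_in and not none_out:
                    out["common"][name].append(pair)
    return out


def random_case(seed):
    rng = np.random.default_rng(seed)
    n_taxa = int(rng.integers(6, 11))
    n_char = int(rng.integers(3, 9))
    data = rng.integers(0, 3, size=(n_taxa, n_char)).astype(np.int8)
    miss = rng.random((n_taxa, n_char)) < 0.15
    data[miss] = MISSING
    taxa = [f"t{i}" for i in range(n_taxa)]
    n_out = int(rng.integers(0, 3))
    m = CharacterMatrix(taxa, data, outgroup_taxa=taxa[n_taxa - n_out:] if n_out else ())
    ingroup = m.ingroup_taxa
    k = int(rng.integers(2, min(4, len(ingroup)) + 1))
    labels = rng.integers(0, k, size=len(ingroup))
    while len(set(labels.tolist())) < k:
        labels = rng.integers(0, k, size=len(ingroup))
    groups = {
        f"g{j}": frozenset(t for t, l in zip(ingroup, labels) if l == j)
        for j in range(k)
    }
    return m, GroupPartition(groups)


@pytest.mark.parametrize("seed", range(20))
def test_diagnosis_matches_literal_rules(seed):
    m, part = random_case(seed)
    got = diagnose_groups(m, part)
    want = literal_diagnosis(m, part)
    assert got.definitive == want["definitive"]
    assert got.exclusive == want["exclusive"]
    assert got.common == want["common"]


def test_handmade_diagnosis():
    #        c1 c2 c3
    # a(g1)  1  1  ?
    # b(g1)  1  0  1
    # c(g2)  0  1  1
    # d(g2)  0  0  1
    data = np.array([[1, 1, MISSING], [1, 0, 1], [0, 1, 1], [0, 0, 1]])
    m = CharacterMatrix(list("abcd"), data)
    part = GroupPartition({"g1": {"a", "b"}, "g2": {"c", "d"}})
    d = diagnose_groups(m, part)
    assert d.definitive["g1"] == [(1, 1)]
    # char 2 state 1: a (g1) and c (g2) share it -> no label for either side
    assert d.exclusive["g1"] == [] and d.exclusive["g2"] == []
    # char 3 state 1 is fixed in every scored ingroup taxon: undiagnostic
    assert d.common["g1"] == [] and d.common["g2"] == []
    assert d.labels_for("g1") == {(1, 1): "definitive"}
    tab = d.to_table()
    assert set(tab.columns) == {"group", "char", "state", "label"}


def test_common_label():
    # state 1 fixed in g1 and present in one g2 taxon (not all ingroup)
    data = np.array([[1], [1], [1], [0]])
    m = CharacterMatrix(list("abcd"), data)
    part = GroupPartition({"g1": {"a", "b"}, "g2": {"c", "d"}})
    d = diagnose_groups(m, part)
    assert d.common["g1"] == [(1, 1)]
    assert d.definitive["g1"] == []


def test_partition_validation():
    with pytest.raises(GroupError, match="overlap"):
        GroupPartition({"g1": {"a"}, "g2": {"a", "b"}})
    m = CharacterMatrix(list("abcd"), np.zeros((4, 2)))
    with pytest.raises(GroupError, match="unknown"):
        GroupPartition({"g1": {"zz"}}).validate_against(m)
    with pytest.raises(GroupError, match="cover"):
        GroupPartition({"g1": {"a", "b"}}).validate_against(m)
    with pytest.raises(GroupError, match="cover"):
        diagnose_groups(m, GroupPartition({"g1": {"a", "b", "c"}}))


def test_monophyly_detects_intruders():
    t = sample_topology(8, seed=3)
    r = t.root_on_edge(t.neighbors(0)[0], 0)
    # a real clade below some internal node
    clade_node = next(
        n for n in r.postorder
        if not r.is_leaf(n) and n != r.root and 2 <= len(r.leafset[n]) <= 4
    )
    clade = {r.taxa[i] for i in r.leafset[clade_node]}
    ok, intruders = monophyly(r, clade)
    assert ok and intruders == []
    # a member plus an outsider: their mrca strictly contains the clade,
    # so the remaining clade members are reported as intruders
    inside = sorted(clade)[0]
    outside = next(t for t in r.taxa if t not in clade)
    ok2, intruders2 = monophyly(r, {inside, outside})
    assert not ok2
    assert set(intruders2) >= clade - {inside}


def test_monophyly_requires_rooted_tree():
    t = sample_topology(6, seed=0)
    with pytest.raises(GroupError, match="rooted"):
        monophyly(t, {"sp01", "sp02"})
    r = t.root_on_edge(t.neighbors(0)[0], 0)
    with pytest.raises(GroupError, match="not in tree"):
        monophyly(r, {"nope"})
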