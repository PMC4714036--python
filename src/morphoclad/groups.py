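"""Species-group diagnosis and monophyly testing.

A group partition divides the ingroup into named, disjoint species groups.
For every derived state y (y != 0, state 0 being the coded plesiomorphy)
of every character, a (character, state) pair is, for a group G:

* **definitive** — every scored member of G has y and no scored taxon
  outside G has it;
* **exclusive** — some but not all scored members of G have y, and no
  scored taxon outside G has it;
* **common** — every scored member of G has y and so do some outsiders,
  *unless* every scored ingroup taxon has y (a subgenus-wide state
  diagnoses nothing and is left unlabeled).

Taxa missing the character are excluded from both quantifiers: a "?" can
neither confirm nor deny presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matrix import MISSING, CharacterMatrix
from .trees import RootedTree, Tree


class GroupError(ValueError):
    pass


@dataclass(frozen=True)
class GroupPartition:
    """Named disjoint taxon sets covering the ingroup."""

    groups: dict  # name -> frozenset of taxon labels

    def __post_init__(self):
        seen: set[str] = set()
        for name, members in self.groups.items():
            members = frozenset(members)
            if seen & members:
                raise GroupError(f"group {name!r} overlaps another group")
            seen |= members
        object.__setattr__(
            self, "groups", {k: frozenset(v) for k, v in self.groups.items()}
        )

    def validate_against(self, matrix: CharacterMatrix) -> None:
        taxa = set(matrix.taxa)
        for name, members in self.groups.items():
            unknown = members - taxa
            if unknown:
                raise GroupError(f"group {name!r} references unknown taxa: {sorted(unknown)}")
        ingroup = set(matrix.ingroup_taxa)
        covered = set().union(*self.groups.values()) if self.groups else set()
        if covered != ingroup:
            missing = sorted(ingroup - covered)
            extra = sorted(covered - ingroup)
            raise GroupError(
                f"partition must cover the ingroup exactly (uncovered: {missing}, "
                f"non-ingroup: {extra})"
            )


@dataclass
class DiagnosisTable:
    """Per group: (character 1-based id, state) pairs by diagnostic label."""

    definitive: dict = field(default_factory=dict)
    exclusive: dict = field(default_factory=dict)
    common: dict = field(default_factory=dict)

    def labels_for(self, group: str):
        out = {}
        for label, table in (
            ("definitive", self.definitive),
            ("exclusive", self.exclusive),
            ("common", self.common),
        ):
            for pair in table.get(group, []):
                out[pair] = label
        return out

    def to_table(self):
        import pandas as pd

        rows = []
        for label, table in (
            ("definitive", self.definitive),
            ("exclusive", self.exclusive),
            ("common", self.common),
        ):
            for group, pairs in table.items():
                for char_id, state in pairs:
                    rows.append(
                        {"group": group, "char": char_id, "state": state, "label": label}
                    )
        return pd.DataFrame(rows, columns=["group", "char", "state", "label"])


def diagnose_groups(matrix: CharacterMatrix, partition: GroupPartition) -> DiagnosisTable:
    """Classify derived states as definitive/exclusive/common per group."""
    partition.validate_against(matrix)
    ingroup = matrix.ingroup_taxa
    table = DiagnosisTable()
    for name in partition.groups:
        table.definitive[name] = []
        table.exclusive[name] = []
        table.common[name] = []
    for c in range(matrix.n_char):
        for y in matrix.char_meta[c].observed_states:
            if y == 0:
                continue
            scored_in = [t for t in ingroup if matrix.cell(t, c) != MISSING]
            has = {t for t in scored_in if matrix.cell(t, c) == y}
            if scored_in and has == set(scored_in):
                continue  # fixed across the whole scored ingroup: undiagnostic
            for name, members in partition.groups.items():
                scored_members = [t for t in members if matrix.cell(t, c) != MISSING]
                if not scored_members:
                    continue
                inside = [t for t in scored_members if t in has]
                outside = [t for t in scored_in if t not in members and t in has]
                pair = (c + 1, int(y))
                if len(inside) == len(scored_members) and not outside:
                    table.definitive[name].append(pair)
                elif 0 < len(inside) < len(scored_members) and not outside:
                    table.exclusive[name].append(pair)
                elif len(inside) == len(scored_members) and outside:
                    table.common[name].append(pair)
    return table


def test_monophyly(tree, group) -> tuple[bool, list]:
    """Is ``group`` a clade of the rooted tree?

    Returns (monophyletic, intruders): the extra taxa inside the group's
    most recent common ancestor when it is not.
    """
    if isinstance(tree, Tree):
        raise GroupError("monophyly is a rooted notion; root the tree first")
    if not isinstance(tree, RootedTree):
        raise GroupError(f"expected a RootedTree, got {type(tree).__name__}")
    group = set(group)
    unknown = group - set(tree.taxa)
    if unknown:
        raise GroupError(f"group taxa not in tree: {sorted(unknown)}")
    ids = {tree.taxa.index(t) for t in group}
    mrca = tree.mrca(ids)
    clade = tree.leafset[mrca]
    intruders = sorted(tree.taxa[i] for i in clade - ids)
    return (not intruders, intruders)
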