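"""Character evolution on a rooted tree.

Given an outgroup-rooted binary tree and a character matrix, this module
enumerates most-parsimonious reconstructions (MPRs), extracts the changes
that are *unambiguous* (identical branch, from-state and to-state in every
MPR), and classifies each as an apomorphy, parallelism, reversal, or
parallel-reversal:

* reversal — the gained state is already assigned to a strict ancestor of
  the branch's parent (a return toward an earlier condition);
* parallelism — the same derived state originates on two or more branches;
* apomorphy — a single origin that never reverts (a later change from the
  derived state to a *new* state, as in a multistate ladder, does not
  spoil it — only a change back to a state ancestral at the origin does).

Branches leading to leaves with missing data can never carry an
unambiguous change for that character: the missing leaf is compatible with
every state, so every such branch admits a change-free reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._mpr import character_dp
from .matrix import CharacterMatrix
from .trees import RootedTree, Tree


class MappingError(ValueError):
    pass


HOMOPLASY_CLASSES = ("apomorphy", "parallelism", "reversal", "parallel-reversal")


@dataclass(frozen=True)
class ChangeRecord:
    """One inferred state transformation on a branch (child-node id)."""

    branch: int
    char: int  # 0-based character index
    from_state: int
    to_state: int
    unambiguous: bool = True
    homoplasy_class: str | None = None
    in_outgroup: bool = False

    @property
    def char_id(self) -> int:
        """1-based character number, as printed in reports."""
        return self.char + 1

    def __post_init__(self):
        if self.from_state == self.to_state:
            raise MappingError("a change must alter the state")


@dataclass
class MPRSet:
    """All most-parsimonious reconstructions of one character."""

    char: int
    min_length: int
    assignments: list  # list of node -> state dicts (original state codes)
    acctran: dict
    deltran: dict

    @property
    def n_mprs(self) -> int:
        return len(self.assignments)


@dataclass
class MappingSummary:
    """Per-character and global counts of unambiguous transformations."""

    per_char: dict = field(default_factory=dict)  # char -> {class: count}
    changes: list = field(default_factory=list)

    @property
    def n_unambiguous(self) -> int:
        return len(self.changes)

    def total(self, cls: str) -> int:
        return sum(c.get(cls, 0) for c in self.per_char.values())

    @property
    def totals(self) -> dict:
        return {cls: self.total(cls) for cls in HOMOPLASY_CLASSES}

    def characters_with(self, *classes) -> list:
        return sorted(
            ch + 1
            for ch, counts in self.per_char.items()
            if any(counts.get(cls, 0) for cls in classes)
        )

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "branch": c.branch,
                    "char": c.char_id,
                    "from": c.from_state,
                    "to": c.to_state,
                    "class": c.homoplasy_class,
                    "in_outgroup": c.in_outgroup,
                }
                for c in self.changes
            ]
        )


def _require_rooted(tree) -> RootedTree:
    if isinstance(tree, Tree):
        raise MappingError(
            "ancestral mapping requires a rooted tree; root on the outgroup "
            "edge first (Tree.root_with_outgroups)"
        )
    if not isinstance(tree, RootedTree):
        raise MappingError(f"expected a RootedTree, got {type(tree).__name__}")
    for node in range(tree.n_nodes):
        if node != tree.root and not tree.is_leaf(node) and len(tree.children[node]) != 2:
            raise MappingError("mapping requires a binary rooted tree")
    return tree


def enumerate_mprs(tree, matrix: CharacterMatrix, char: int, cap: int = 100000) -> MPRSet:
    """Every minimum-length ancestral assignment for one character.

    The ACCTRAN-style (changes accelerated toward the root) and
    DELTRAN-style (changes delayed toward the tips) members are computed
    directly and are always elements of the enumerated set.
    """
    rtree = _require_rooted(tree)
    dp = character_dp(rtree, matrix, char)

    def decode(assign):
        return {node: dp.state_of[s] for node, s in assign.items()}

    return MPRSet(
        char=char,
        min_length=dp.min_length,
        assignments=[decode(a) for a in dp.enumerate(cap=cap)],
        acctran=decode(dp.greedy(accelerate=True)),
        deltran=decode(dp.greedy(accelerate=False)),
    )


def _outgroup_side(rtree: RootedTree, matrix: CharacterMatrix) -> frozenset[int]:
    """Node ids on the outgroup side of the root (empty if no outgroups)."""
    og = {rtree.taxa.index(t) for t in matrix.outgroup_taxa if t in rtree.taxa}
    if not og:
        return frozenset()
    for child in rtree.children[rtree.root]:
        leafset = rtree.leafset[child]
        if og <= leafset:
            nodes = {child}
            stack = [child]
            while stack:
                x = stack.pop()
                for c in rtree.children[x]:
                    nodes.add(c)
                    stack.append(c)
            return frozenset(nodes)
    return frozenset()


def unambiguous_changes(tree, matrix: CharacterMatrix) -> list[ChangeRecord]:
    """Changes implied identically by every MPR of their character.

    A change is emitted for branch b and character i iff the set of
    edge-optimal (parent-state, child-state) pairs on b is a single pair
    with differing states; ambiguous branches yield nothing.
    """
    rtree = _require_rooted(tree)
    og_side = _outgroup_side(rtree, matrix)
    out: list[ChangeRecord] = []
    for c in range(matrix.n_char):
        dp = character_dp(rtree, matrix, c)
        for node in rtree.preorder:
            if node == rtree.root:
                continue
            pairs = dp.edge_pairs(node)
            if len(pairs) == 1:
                (ps, cs) = next(iter(pairs))
                if ps != cs:
                    out.append(
                        ChangeRecord(
                            branch=node,
                            char=c,
                            from_state=dp.state_of[ps],
                            to_state=dp.state_of[cs],
                            in_outgroup=node in og_side,
                        )
                    )
    return out


def classify_changes(changes, tree, matrix: CharacterMatrix) -> MappingSummary:
    """Classify unambiguous changes against a reference MPR history.

    The DELTRAN-style history anchors ancestor states and derived-state
    origin counts; changes on the outgroup side of the root are excluded
    from the homoplasy classing of ingroup character evolution (they are
    kept in the record list, unclassified).
    """
    rtree = _require_rooted(tree)
    summary = MappingSummary()
    by_char: dict[int, list[ChangeRecord]] = {}
    for ch in changes:
        by_char.setdefault(ch.char, []).append(ch)
    for c, recs in sorted(by_char.items()):
        dp = character_dp(rtree, matrix, c)
        assign = dp.greedy(accelerate=False)
        decode = dp.state_of
        # all changes in the reference history (origins may be ambiguous
        # elsewhere; the reference fixes one consistent global picture)
        hist = {
            node: (decode[assign[rtree.parent[node]]], decode[assign[node]])
            for node in rtree.preorder
            if node != rtree.root and assign[rtree.parent[node]] != assign[node]
        }
        origins: dict[int, int] = {}
        for _, (fs, ts) in hist.items():
            origins[ts] = origins.get(ts, 0) + 1
        counts: dict[str, int] = {}
        for rec in recs:
            if rec.in_outgroup:
                summary.changes.append(rec)
                continue
            parent = rtree.parent[rec.branch]
            anc_states = {decode[assign[a]] for a in rtree.ancestors(parent)}
            path_states = anc_states | {decode[assign[parent]]}
            is_reversal = rec.to_state in anc_states
            is_parallel = origins.get(rec.to_state, 1) >= 2
            if not is_reversal and not is_parallel:
                # a descendant change from the derived state back to a
                # state ancestral at the origin is a reversion
                desc = _descendants(rtree, rec.branch)
                reverted = any(
                    node in hist
                    and hist[node][0] == rec.to_state
                    and hist[node][1] in path_states
                    for node in desc
                )
                cls = "apomorphy" if not reverted else "reversal"
            elif is_reversal and is_parallel:
                cls = "parallel-reversal"
            elif is_reversal:
                cls = "reversal"
            else:
                cls = "parallelism"
            classified = ChangeRecord(
                branch=rec.branch,
                char=rec.char,
                from_state=rec.from_state,
                to_state=rec.to_state,
                unambiguous=rec.unambiguous,
                homoplasy_class=cls,
                in_outgroup=False,
            )
            summary.changes.append(classified)
            counts[cls] = counts.get(cls, 0) + 1
        if counts:
            summary.per_char[c] = counts
    return summary


def _descendants(rtree: RootedTree, node: int) -> set[int]:
    out = set()
    stack = list(rtree.children[node])
    while stack:
        x = stack.pop()
        out.add(x)
        stack.extend(rtree.children[x])
    return out


def map_characters(tree, matrix: CharacterMatrix) -> MappingSummary:
    """Convenience: unambiguous changes plus their classification."""
    return classify_changes(unambiguous_changes(tree, matrix), tree, matrix)


def annotated_newick(tree, matrix: CharacterMatrix, changes=None) -> str:
    """Newick with per-branch change strings ("char:from>to") as comments."""
    rtree = _require_rooted(tree)
    if changes is None:
        changes = unambiguous_changes(rtree, matrix)
    per_branch: dict[int, list[str]] = {}
    for ch in changes:
        per_branch.setdefault(ch.branch, []).append(
            f"{ch.char_id}:{ch.from_state}>{ch.to_state}"
        )
    labels = {b: "[" + " ".join(sorted(v)) + "]" for b, v in per_branch.items()}
    return rtree.to_newick(labels=labels)
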