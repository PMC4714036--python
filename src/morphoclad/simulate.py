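"""Synthetic trees and character matrices for end-to-end testing.

The generator emulates the statistical shape of a small-bodied carabid
morphological study: a couple dozen taxa, a few dozen unordered binary
(plus one or two three-state) characters coded with plesiomorphy 0,
outgroups branching near the root, and rectangular missing blocks for
taxa whose male endophallus or female genitalia were never dissected.

The change process is per-branch Bernoulli rather than continuous-time
Markov: every character changes on every branch independently with
probability ``p``, moving to a uniformly chosen different state.  That
keeps the expected amount of homoplasy directly tunable and matches the
cladogram-like nature of presence/absence codings.  All randomness flows
from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, CharacterMatrix
from .trees import Tree


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the per-branch Bernoulli change process."""

    n_taxa: int
    n_char: int
    state_counts: tuple = ()  # per character; empty = all binary
    p: float = 0.05
    missing_blocks: tuple = ()  # ((taxon ids/labels...), (char indices...)) pairs
    outgroup_count: int = 0
    ensure_variable: bool = False  # redraw until every character varies
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise SimulationError("change probability p must be in [0, 1]")
        counts = tuple(self.state_counts) or (2,) * self.n_char
        if len(counts) != self.n_char:
            raise SimulationError("state_counts length must equal n_char")
        if any(k < 2 for k in counts):
            raise SimulationError("state counts must be >= 2")
        object.__setattr__(self, "state_counts", counts)


def default_taxa(n_taxa: int, outgroup_count: int = 0) -> list[str]:
    n_in = n_taxa - outgroup_count
    taxa = [f"sp{i + 1:02d}" for i in range(n_in)]
    taxa += [f"out{i + 1}" for i in range(outgroup_count)]
    return taxa


def sample_topology(n_taxa: int, seed=0, taxa=None) -> Tree:
    """Uniform random unrooted binary topology by sequential leaf insertion.

    Each new leaf subdivides an edge chosen uniformly at random, which
    yields the uniform distribution over labeled topologies.
    """
    if n_taxa < 4:
        raise SimulationError("need at least 4 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if taxa is None:
        taxa = default_taxa(n_taxa)
    if len(taxa) != n_taxa:
        raise SimulationError("taxa list length must equal n_taxa")
    nbrs: list[list[int]] = [[] for _ in range(n_taxa)]
    hub = n_taxa
    nbrs.append([0, 1, 2])
    for leaf in range(3):
        nbrs[leaf] = [hub]
    edges = [(0, hub), (1, hub), (2, hub)]
    next_id = n_taxa + 1
    for leaf in range(3, n_taxa):
        u, v = edges[rng.integers(0, len(edges))]
        w = next_id
        next_id += 1
        nbrs.append([u, v, leaf])
        nbrs[u] = [w if x == v else x for x in nbrs[u]]
        nbrs[v] = [w if x == u else x for x in nbrs[v]]
        nbrs[leaf] = [w]
        edges.remove((u, v))
        edges.extend([(u, w), (v, w), (leaf, w)])
    return Tree(taxa, nbrs)


def evolve_matrix(tree: Tree, config: SimConfig, root_edge=None) -> CharacterMatrix:
    """Evolve characters down the tree from an all-0 root.

    The returned matrix carries a ``change_log`` attribute: one entry per
    realized change with the leaf-label clade below the branch, the
    character, and the from/to states (the oracle for ancestral-state
    recovery tests).
    """
    if tree.n_leaves != config.n_taxa:
        raise SimulationError(
            f"tree has {tree.n_leaves} leaves, config says {config.n_taxa}"
        )
    rng = np.random.default_rng(config.seed)
    if root_edge is None:
        leaf0 = 0
        root_edge = (tree.neighbors(leaf0)[0], leaf0)
    rtree = tree.root_on_edge(*root_edge)
    data = np.zeros((config.n_taxa, config.n_char), dtype=np.int8)
    change_log: list[dict] = []
    for c, k in enumerate(config.state_counts):
        states = _evolve_char(rtree, k, config.p, rng)
        if config.ensure_variable:
            # study-style matrices carry no invariant characters: redraw
            # until at least two states appear among the leaves
            for _ in range(200):
                if len({states[leaf] for leaf in range(config.n_taxa)}) >= 2:
                    break
                states = _evolve_char(rtree, k, config.p, rng)
        for leaf in range(config.n_taxa):
            data[leaf, c] = states[leaf]
        for node in rtree.preorder:
            if node == rtree.root:
                continue
            a, b = states[rtree.parent[node]], states[node]
            if a != b:
                change_log.append(
                    {
                        "clade": frozenset(
                            rtree.taxa[i] for i in rtree.leafset[node]
                        ),
                        "char": c,
                        "from": int(a),
                        "to": int(b),
                    }
                )
    _apply_missing(data, tree.taxa, config.missing_blocks)
    outgroups = tree.taxa[config.n_taxa - config.outgroup_count :] if config.outgroup_count else ()
    matrix = CharacterMatrix(tree.taxa, data, outgroups)
    matrix.change_log = change_log
    return matrix


def _evolve_char(rtree, k: int, p: float, rng) -> dict[int, int]:
    states = {rtree.root: 0}
    for node in rtree.preorder:
        if node == rtree.root:
            continue
        s = states[rtree.parent[node]]
        if rng.random() < p:
            alts = [x for x in range(k) if x != s]
            s = int(alts[rng.integers(0, len(alts))])
        states[node] = s
    return states


def _apply_missing(data, taxa, missing_blocks):
    index = {t: i for i, t in enumerate(taxa)}
    for block_taxa, block_chars in missing_blocks:
        for t in block_taxa:
            i = index[t] if isinstance(t, str) else int(t)
            if not 0 <= i < data.shape[0]:
                raise SimulationError(f"missing block references unknown taxon {t!r}")
            for c in block_chars:
                if not 0 <= c < data.shape[1]:
                    raise SimulationError(f"missing block references unknown character {c}")
                data[i, c] = MISSING


# ---------------------------------------------------------------------------
# the study-shaped preset
# ---------------------------------------------------------------------------

#: 36 characters: 10 external, 11 male genital, 9 endophallus, 6 female
#: genital; characters 13 and 22 (1-based) are three-state.
PAPERLIKE_N_INGROUP = 23
PAPERLIKE_N_CHAR = 36
PAPERLIKE_THREE_STATE = (12, 21)  # 0-based
ENDOPHALLUS_CHARS = tuple(range(21, 30))  # 1-based 22..30
FEMALE_CHARS = tuple(range(30, 36))  # 1-based 31..36
N_ENDOPHALLUS_UNKNOWN = 6
N_FEMALE_UNKNOWN = 4
#: Per-branch change probability chosen so a character changes ~3 times on
#: a 25-taxon tree (47 branches), the homoplasy level of a morphological
#: matrix with ensemble CI around 0.4.
PAPERLIKE_P = 0.065


def make_paperlike(seed: int = 0):
    """A truth tree and matrix shaped like the study's data.

    25 taxa (23 ingroup + an outgroup pair attached as a cherry, so the
    tree roots cleanly on the branch joining the two outgroups), 36
    characters with the two canonical three-state characters, a 9-character
    endophallus block missing for 6 ingroup taxa and a 6-character female
    block missing for 4.  Character evolution starts at the all-0 root on
    the outgroup edge, so outgroup rows stay predominantly plesiomorphic.
    Every character is guaranteed variable after masking (the study matrix
    contains no invariant characters); the three-state characters are
    guaranteed to show all three states.
    """
    rng = np.random.default_rng(seed)
    n_in = PAPERLIKE_N_INGROUP
    taxa = default_taxa(n_in + 2, outgroup_count=2)
    # ingroup topology on leaf ids 0..22 with internal ids >= 25
    in_tree = sample_topology(n_in, rng, taxa=[taxa[i] for i in range(n_in)])
    shift = 2  # make room for the two outgroup leaf ids
    nbrs: list[list[int]] = [[] for _ in range(n_in + 2)]
    for node in range(in_tree.n_nodes):
        tgt = node if node < n_in else node + shift
        while len(nbrs) <= tgt:
            nbrs.append([])
        nbrs[tgt] = [x if x < n_in else x + shift for x in in_tree.neighbors(node)]
    # attach the outgroup cherry on a uniformly chosen ingroup edge
    edges = [(u, v) for u in range(len(nbrs)) for v in nbrs[u] if u < v]
    u, v = edges[rng.integers(0, len(edges))]
    w1, w2 = len(nbrs), len(nbrs) + 1
    nbrs.append([u, v, w2])  # w1 subdivides (u, v)
    nbrs.append([w1, n_in, n_in + 1])  # w2 carries the outgroup cherry
    nbrs[u] = [w1 if x == v else x for x in nbrs[u]]
    nbrs[v] = [w1 if x == u else x for x in nbrs[v]]
    nbrs[n_in] = [w2]
    nbrs[n_in + 1] = [w2]
    tree = Tree(taxa, nbrs)

    state_counts = tuple(
        3 if c in PAPERLIKE_THREE_STATE else 2 for c in range(PAPERLIKE_N_CHAR)
    )
    endo_unknown = sorted(
        rng.choice(n_in, size=N_ENDOPHALLUS_UNKNOWN, replace=False).tolist()
    )
    fem_unknown = sorted(
        rng.choice(n_in, size=N_FEMALE_UNKNOWN, replace=False).tolist()
    )
    config = SimConfig(
        n_taxa=n_in + 2,
        n_char=PAPERLIKE_N_CHAR,
        state_counts=state_counts,
        p=PAPERLIKE_P,
        missing_blocks=(
            (tuple(endo_unknown), ENDOPHALLUS_CHARS),
            (tuple(fem_unknown), FEMALE_CHARS),
        ),
        outgroup_count=2,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    rtree = tree.root_on_edge(w1, w2)
    data = np.zeros((config.n_taxa, config.n_char), dtype=np.int8)
    rng2 = np.random.default_rng(config.seed)
    change_log: list[dict] = []
    masked_rows = {
        c: set(endo_unknown if c in ENDOPHALLUS_CHARS else fem_unknown)
        for c in ENDOPHALLUS_CHARS + FEMALE_CHARS
    }
    for c, k in enumerate(config.state_counts):
        visible = [i for i in range(config.n_taxa) if i not in masked_rows.get(c, ())]
        for _ in range(200):
            states = _evolve_char(rtree, k, config.p, rng2)
            observed = {states[i] for i in visible}
            if len(observed) == k:
                break
        for leaf in range(config.n_taxa):
            data[leaf, c] = states[leaf]
        for node in rtree.preorder:
            if node == rtree.root:
                continue
            a, b = states[rtree.parent[node]], states[node]
            if a != b:
                change_log.append(
                    {
                        "clade": frozenset(rtree.taxa[i] for i in rtree.leafset[node]),
                        "char": c,
                        "from": int(a),
                        "to": int(b),
                    }
                )
    _apply_missing(data, taxa, config.missing_blocks)
    matrix = CharacterMatrix(taxa, data, (taxa[n_in], taxa[n_in + 1]))
    matrix.change_log = change_log
    matrix.sim_config = config
    return tree, matrix


def partition_from_tree(tree: Tree, matrix: CharacterMatrix, n_groups: int = 4):
    """Cut the ingroup part of the rooted truth tree into ``n_groups``
    clades (splitting the largest clade repeatedly), for group-diagnosis
    demos where the grouping should reflect the true topology."""
    from .groups import GroupPartition

    rtree = tree.root_with_outgroups(matrix.outgroup_taxa)
    og = set(matrix.outgroup_taxa)
    ingroup_side = [
        ch
        for ch in rtree.children[rtree.root]
        if not ({rtree.taxa[i] for i in rtree.leafset[ch]} & og)
    ]
    parts = list(ingroup_side)
    while len(parts) < n_groups:
        big = max(parts, key=lambda nd: len(rtree.leafset[nd]))
        if rtree.is_leaf(big):
            break
        parts.remove(big)
        parts.extend(rtree.children[big])
    groups = {
        f"group{i + 1}": frozenset(rtree.taxa[x] for x in rtree.leafset[nd])
        for i, nd in enumerate(sorted(parts, key=lambda nd: -len(rtree.leafset[nd])))
    }
    return GroupPartition(groups)
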