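"""Most-parsimonious tree search.

The heuristic regime follows classic PAUP-style practice: random-addition
stepwise starting trees (a beam of ``hold`` partial trees per step), TBR
branch swapping to a local optimum (first-improvement unless steepest
descent is requested), equally-best trees accumulated across replicates
and completed by a walk over equal-length TBR neighbors (MulTrees), then
deduplicated after collapsing internal branches whose minimum possible
length is zero.  ``branch_and_bound`` provides the exact optimum (all
optimal trees) for small instances and serves as the heuristic's oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._mpr import character_dp
from .matrix import CharacterMatrix
from .parsimony import as_weights, leaf_masks_for
from .trees import Tree

_EPS = 1e-9
_HARD_TREE_CAP = 10000


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class SearchConfig:
    """Heuristic-search parameters (PAUP-style)."""

    n_replicates: int = 20
    hold: int = 1
    swap: str = "tbr"
    maxtrees: int = 100
    auto_extend: bool = True
    multrees: bool = True
    steepest_descent: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1 or self.hold < 1 or self.maxtrees < 1:
            raise SearchError("n_replicates, hold and maxtrees must be >= 1")
        if self.swap != "tbr":
            raise SearchError(f"unsupported swap algorithm {self.swap!r}")


@dataclass
class SearchResult:
    """Outcome of a tree search.

    ``trees`` are the distinct best trees after zero-minimum-length branch
    collapse (possibly multifurcating); ``binary_trees`` the underlying
    distinct binary topologies, each scoring exactly ``best_length``.
    """

    best_length: float
    trees: list = field(default_factory=list)
    binary_trees: list = field(default_factory=list)
    replicate_log: list = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def log_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"replicate": range(len(self.replicate_log)), "best_length": self.replicate_log}
        )


# ---------------------------------------------------------------------------
# stepwise addition (beam version; hold=1 is JIT-compiled)
# ---------------------------------------------------------------------------


def _canonical_partial(nbr: np.ndarray, start_leaf: int, n_leaves: int) -> str:
    """Canonical newick-like key of a (possibly partial) binary tree."""

    def sub(node: int, parent: int) -> str:
        if node < n_leaves:
            return f"L{node}"
        parts = sorted(
            sub(int(x), node) for x in nbr[node] if x >= 0 and x != parent
        )
        return "(" + ",".join(parts) + ")"

    hub = int(nbr[start_leaf, 0])
    parts = sorted([f"L{start_leaf}"] + [
        sub(int(x), hub) for x in nbr[hub] if x >= 0 and x != start_leaf
    ])
    return "(" + ",".join(parts) + ")"


def _resolve_order(matrix: CharacterMatrix, order) -> np.ndarray:
    ids = [matrix.taxon_index(t) if isinstance(t, str) else int(t) for t in order]
    if sorted(ids) != list(range(matrix.n_taxa)):
        raise SearchError("addition order is not a permutation of the matrix taxa")
    return np.asarray(ids, dtype=np.int64)


def _beam_stepwise(masks, weights, order, hold):
    """Beam-search stepwise addition; returns list of (length, nbr)."""
    n_leaves = masks.shape[0]
    n_nodes = 2 * n_leaves - 2
    o0, o1, o2 = int(order[0]), int(order[1]), int(order[2])
    nbr0 = np.full((n_nodes, 3), -1, np.int32)
    hub = n_leaves
    nbr0[hub] = (o0, o1, o2)
    nbr0[o0, 0] = nbr0[o1, 0] = nbr0[o2, 0] = hub
    held = [nbr0]
    for k in range(3, n_leaves):
        leaf = int(order[k])
        w_new = n_leaves + k - 2
        cand: dict[str, tuple[float, np.ndarray]] = {}
        for nbr in held:
            edges = [
                (x, int(y))
                for x in range(n_nodes)
                for y in nbr[x]
                if y >= 0 and y > x
            ]
            for x, y in edges:
                c = nbr.copy()
                c[w_new] = (x, y, leaf)
                c[x][c[x] == y] = w_new
                c[y][c[y] == x] = w_new
                c[leaf, 0] = w_new
                L = float(_kernels.fitch_wlen(c, masks, weights, o0))
                key = _canonical_partial(c, o0, n_leaves)
                if key not in cand or L < cand[key][0] - _EPS:
                    cand[key] = (L, c)
        ranked = sorted(cand.items(), key=lambda kv: (kv[1][0], kv[0]))
        held = [c for _, (_, c) in ranked[:hold]]
    final = []
    for nbr in held:
        final.append((float(_kernels.fitch_wlen(nbr, masks, weights, 0)), nbr))
    final.sort(key=lambda t: (t[0], _canonical_partial(t[1], 0, n_leaves)))
    return final


def stepwise_addition(matrix: CharacterMatrix, weights=None, order=None, hold: int = 1):
    """Build starting trees by stepwise addition in the given taxon order.

    Returns the final held set (up to ``hold`` trees) sorted by
    (length, canonical topology).
    """
    if matrix.n_taxa < 4:
        raise SearchError("stepwise addition needs at least 4 taxa")
    if order is None:
        order = list(range(matrix.n_taxa))
    ids = _resolve_order(matrix, order)
    w = as_weights(weights, matrix.n_char)
    masks = leaf_masks_for(matrix, matrix.taxa)
    final = _beam_stepwise(masks, w, ids, hold)
    return [Tree.from_kernel(nbr, matrix.taxa) for _, nbr in final]


# ---------------------------------------------------------------------------
# TBR swapping and the heuristic search
# ---------------------------------------------------------------------------


def _swap_to_local_opt(nbr, masks, weights, L, steepest: bool) -> float:
    while True:
        L2 = float(_kernels.tbr_pass(nbr, masks, weights, L, steepest))
        if L2 < L - _EPS:
            L = L2
        else:
            return L


def _collect_plateau(best_nbrs, masks, weights, L, cap, auto_extend):
    """Complete the MPT set by walking equal-length TBR neighbors."""
    n_nodes = best_nbrs[0].shape[0]
    n_leaves = masks.shape[0]
    seen = {}
    queue = []
    for nbr in best_nbrs:
        key = _canonical_partial(nbr, 0, n_leaves)
        if key not in seen:
            seen[key] = nbr
            queue.append(nbr)
    buf = np.empty((1024, n_nodes, 3), np.int32)
    i = 0
    while i < len(queue):
        if len(seen) >= cap:
            if auto_extend and cap < _HARD_TREE_CAP:
                cap = min(cap * 2, _HARD_TREE_CAP)
            else:
                break
        nbr = queue[i]
        i += 1
        cnt = int(_kernels.tbr_equal_neighbors(nbr, masks, weights, L, buf))
        for j in range(cnt):
            cand = buf[j].copy()
            key = _canonical_partial(cand, 0, n_leaves)
            if key not in seen:
                seen[key] = cand
                queue.append(cand)
                if len(seen) >= cap and not auto_extend:
                    break
    return list(seen.values())


def min_length_zero_edges(tree: Tree, matrix: CharacterMatrix):
    """Internal edges whose minimum possible length over MPRs is zero for
    every character (the classic collapse rule for ambiguous branches)."""
    rtree = tree.root_on_edge(0, tree.neighbors(0)[0])
    dps = [character_dp(rtree, matrix, c) for c in range(matrix.n_char)]
    zero = []
    for node in rtree.postorder:
        par = rtree.parent[node]
        if par in (-1, rtree.root) or rtree.is_leaf(node):
            continue
        if all(dp.edge_min_changes(node) == 0 for dp in dps):
            zero.append((par, node))
    return zero


def collapse_zero_length(tree: Tree, matrix: CharacterMatrix) -> Tree:
    """Collapse internal branches of minimum length zero (may multifurcate)."""
    zero = min_length_zero_edges(tree, matrix)
    if not zero:
        return tree
    return tree.collapse_edges(zero)


def heuristic_search(
    matrix: CharacterMatrix, weights=None, config: SearchConfig | None = None
) -> SearchResult:
    """Random-addition + TBR heuristic search for most-parsimonious trees."""
    if config is None:
        config = SearchConfig()
    if matrix.n_taxa < 4:
        raise SearchError("search needs at least 4 taxa")
    w = as_weights(weights, matrix.n_char)
    masks = leaf_masks_for(matrix, matrix.taxa)
    rng = np.random.default_rng(config.seed)
    n = matrix.n_taxa
    best_len = np.inf
    best_nbrs: list[np.ndarray] = []
    best_keys: set[str] = set()
    log = []
    for _ in range(config.n_replicates):
        order = rng.permutation(n).astype(np.int64)
        if config.hold == 1:
            nbr = np.asarray(_kernels.greedy_stepwise(order, masks, w))
            L = float(_kernels.fitch_wlen(nbr, masks, w, 0))
        else:
            L, nbr = _beam_stepwise(masks, w, order, config.hold)[0]
            nbr = nbr.copy()
        L = _swap_to_local_opt(nbr, masks, w, L, config.steepest_descent)
        log.append(L)
        if L < best_len - _EPS:
            best_len = L
            best_nbrs = [nbr]
            best_keys = {_canonical_partial(nbr, 0, n)}
        elif abs(L - best_len) <= _EPS:
            key = _canonical_partial(nbr, 0, n)
            if key not in best_keys and len(best_nbrs) < config.maxtrees:
                best_keys.add(key)
                best_nbrs.append(nbr)
    if config.multrees:
        best_nbrs = _collect_plateau(
            best_nbrs, masks, w, best_len, config.maxtrees, config.auto_extend
        )
    return _finalize(best_nbrs, best_len, log, matrix)


def _finalize(best_nbrs, best_len, log, matrix) -> SearchResult:
    binary = [Tree.from_kernel(nbr, matrix.taxa) for nbr in best_nbrs]
    collapsed: dict[frozenset, Tree] = {}
    for t in binary:
        ct = collapse_zero_length(t, matrix)
        collapsed.setdefault(ct.bipartitions, ct)
    return SearchResult(
        best_length=float(best_len),
        trees=list(collapsed.values()),
        binary_trees=binary,
        replicate_log=log,
    )


# ---------------------------------------------------------------------------
# exact search
# ---------------------------------------------------------------------------


def branch_and_bound(
    matrix: CharacterMatrix, weights=None, use_bound: bool = True
) -> SearchResult:
    """Exact search by bounded enumeration of unrooted topologies.

    Taxa are added in matrix order; a partial tree whose length already
    exceeds the incumbent is pruned (Fitch length is non-decreasing under
    leaf addition).  Returns every optimal tree.  Refuses more than 12
    taxa.  With ``use_bound=False`` the full enumeration is performed and
    ``result.n_visited`` counts the complete topologies examined.
    """
    n = matrix.n_taxa
    if n > 12:
        raise SearchError(f"branch_and_bound limited to 12 taxa, got {n}")
    if n < 4:
        raise SearchError("need at least 4 taxa")
    w = as_weights(weights, matrix.n_char)
    masks = leaf_masks_for(matrix, matrix.taxa)
    n_nodes = 2 * n - 2
    nbr = np.full((n_nodes, 3), -1, np.int32)
    hub = n
    nbr[hub] = (0, 1, 2)
    nbr[0, 0] = nbr[1, 0] = nbr[2, 0] = hub
    state = {"best": np.inf, "trees": [], "keys": set(), "visited": 0}

    def rec(k: int):
        if k == n:
            L = float(_kernels.fitch_wlen(nbr, masks, w, 0))
            state["visited"] += 1
            if L < state["best"] - _EPS:
                state["best"] = L
                state["trees"] = [nbr.copy()]
                state["keys"] = {_canonical_partial(nbr, 0, n)}
            elif abs(L - state["best"]) <= _EPS:
                key = _canonical_partial(nbr, 0, n)
                if key not in state["keys"]:
                    state["keys"].add(key)
                    state["trees"].append(nbr.copy())
            return
        if use_bound and np.isfinite(state["best"]):
            L = float(_kernels.fitch_wlen(nbr, masks, w, 0))
            if L > state["best"] + _EPS:
                return
        leaf = k
        w_new = n + k - 2
        edges = [
            (x, int(y)) for x in range(n_nodes) for y in nbr[x] if y >= 0 and y > x
        ]
        for x, y in edges:
            nbr[w_new] = (x, y, leaf)
            nbr[x][nbr[x] == y] = w_new
            nbr[y][nbr[y] == x] = w_new
            nbr[leaf, 0] = w_new
            rec(k + 1)
            nbr[x][nbr[x] == w_new] = y
            nbr[y][nbr[y] == w_new] = x
            nbr[w_new] = -1
            nbr[leaf, 0] = -1

    rec(3)
    result = _finalize(state["trees"], state["best"], [], matrix)
    result.n_visited = state["visited"]
    return result
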