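"""Tree-set summaries: strict and majority-rule consensus, bootstrap support.

Bipartitions (splits) are canonicalized as the taxon set on the side away
from a fixed reference taxon, so orientation never matters.  Bootstrap
support for a split is the percentage of character-resampling replicates
whose most-parsimonious tree set contains it, each replicate contributing
a total weight of one split equally among its equally-best trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .matrix import CharacterMatrix
from .parsimony import as_weights, leaf_masks_for
from .search import SearchConfig, _canonical_partial, _swap_to_local_opt
from .trees import Tree, TreeError


class ConsensusError(ValueError):
    pass


@dataclass
class SupportTable:
    """Split -> support percentage (0..100), with the replicate count."""

    support: dict = field(default_factory=dict)
    n_replicates: int = 0

    def get(self, taxa_subset, default=0.0) -> float:
        return self.support.get(frozenset(taxa_subset), default)

    def to_table(self):
        import pandas as pd

        rows = [
            {"split": "|".join(sorted(k)), "support_pct": v}
            for k, v in sorted(self.support.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows, columns=["split", "support_pct"])


def _check_leafsets(trees) -> list:
    trees = list(trees)
    if not trees:
        raise ConsensusError("empty tree set")
    ref = set(trees[0].taxa)
    for t in trees[1:]:
        if set(t.taxa) != ref:
            raise ConsensusError("trees have mismatched leaf sets")
    return trees


def tree_from_splits(taxa, splits) -> Tree:
    """Build the (possibly multifurcating) tree displaying a compatible
    split set.  Splits are taxon subsets not containing ``taxa[0]``."""
    taxa = tuple(taxa)
    ref = taxa[0]
    clusters = sorted({frozenset(s) for s in splits}, key=len, reverse=True)
    for c in clusters:
        if ref in c or not (2 <= len(c) <= len(taxa) - 2):
            raise ConsensusError(f"not a valid nontrivial split: {sorted(c)}")
    n = len(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    # parent cluster = smallest strictly-containing cluster (root otherwise)
    node_of = {}
    nbrs: list[list[int]] = [[] for _ in range(n)]
    root = n
    nbrs.append([])
    next_id = n + 1
    for c in clusters:
        node_of[c] = next_id
        nbrs.append([])
        next_id += 1

    def parent_node(c):
        best = None
        for d in clusters:
            if c < d and (best is None or len(d) < len(best)):
                best = d
        return node_of[best] if best is not None else root

    for c in clusters:
        p = parent_node(c)
        nbrs[node_of[c]].append(p)
        nbrs[p].append(node_of[c])
    for t in taxa:
        containing = [c for c in clusters if t in c]
        if containing:
            smallest = min(containing, key=len)
            p = node_of[smallest]
        else:
            p = root
        nbrs[index[t]].append(p)
        nbrs[p].append(index[t])
    return Tree(taxa, nbrs)


def strict_consensus(trees) -> Tree:
    """The tree containing exactly the splits present in every input tree."""
    trees = _check_leafsets(trees)
    common = frozenset.intersection(*(t.bipartitions for t in trees))
    return tree_from_splits(trees[0].taxa, common)


def majority_consensus(trees, threshold: float = 50.0):
    """Keep splits whose frequency strictly exceeds ``threshold`` percent.

    Thresholds below 50 are refused (conflicting splits could both pass).
    Returns the consensus tree and the frequency table of retained splits.
    """
    if threshold < 50:
        raise ConsensusError("majority threshold below 50% can admit conflicts")
    trees = _check_leafsets(trees)
    counts: dict = {}
    for t in trees:
        for split in t.bipartitions:
            counts[split] = counts.get(split, 0) + 1
    pct = {s: 100.0 * c / len(trees) for s, c in counts.items()}
    kept = {s: p for s, p in pct.items() if p > threshold}
    tree = tree_from_splits(trees[0].taxa, kept.keys())
    return tree, SupportTable(support=kept, n_replicates=len(trees))


def support_newick(tree: Tree, table: SupportTable, decimals: int = 0) -> str:
    """Newick with support percentages as internal-node labels."""
    labels = {}
    n = tree.n_leaves
    for u, v in tree.edges():
        if u < n or v < n:
            continue
        for child in (u, v):
            side = tree.leaves_behind(u + v - child, child)
            key = frozenset(tree.taxa[i] for i in side)
            if 0 in side:
                key = frozenset(tree.taxa) - key
            if key in table.support:
                labels[child] = f"{table.support[key]:.{decimals}f}"
    return tree.to_newick(labels=labels)


def bootstrap_support(
    matrix: CharacterMatrix,
    weights=None,
    search_config: SearchConfig | None = None,
    n_boot: int = 100,
    seed: int = 0,
) -> SupportTable:
    """Nonparametric bootstrap: resample characters with replacement (their
    weights travel with them), search each pseudo-matrix, and tally splits.
    """
    if n_boot < 1:
        raise ConsensusError("n_boot must be >= 1")
    if search_config is None:
        search_config = SearchConfig(n_replicates=10, hold=1, maxtrees=16)
    w0 = as_weights(weights, matrix.n_char)
    masks0 = leaf_masks_for(matrix, matrix.taxa)
    n = matrix.n_taxa
    rng = np.random.default_rng(seed)
    acc: dict = {}
    buf = np.empty((search_config.maxtrees, 2 * n - 2, 3), np.int32)
    for _ in range(n_boot):
        idx = rng.integers(0, matrix.n_char, matrix.n_char)
        masks = np.ascontiguousarray(masks0[:, idx])
        w = np.ascontiguousarray(w0[idx])
        best_len = np.inf
        best: dict[str, np.ndarray] = {}
        for _ in range(search_config.n_replicates):
            order = rng.permutation(n).astype(np.int64)
            nbr = np.asarray(_kernels.greedy_stepwise(order, masks, w))
            L = float(_kernels.fitch_wlen(nbr, masks, w, 0))
            L = _swap_to_local_opt(nbr, masks, w, L, search_config.steepest_descent)
            if L < best_len - 1e-9:
                best_len = L
                best = {_canonical_partial(nbr, 0, n): nbr}
            elif abs(L - best_len) <= 1e-9 and len(best) < search_config.maxtrees:
                best.setdefault(_canonical_partial(nbr, 0, n), nbr)
        if search_config.multrees:
            # complete the replicate's MPT set by an equal-length walk
            queue = list(best.values())
            i = 0
            while i < len(queue) and len(best) < search_config.maxtrees:
                cnt = int(
                    _kernels.tbr_equal_neighbors(queue[i], masks, w, best_len, buf)
                )
                i += 1
                for j in range(cnt):
                    cand = buf[j].copy()
                    key = _canonical_partial(cand, 0, n)
                    if key not in best:
                        best[key] = cand
                        queue.append(cand)
                        if len(best) >= search_config.maxtrees:
                            break
        share = 1.0 / len(best)
        for nbr in best.values():
            for split in Tree.from_kernel(nbr, matrix.taxa).bipartitions:
                acc[split] = acc.get(split, 0.0) + share
    return SupportTable(
        support={s: 100.0 * c / n_boot for s, c in acc.items()},
        n_replicates=n_boot,
    )
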