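"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's Fitch/DP machinery:
tree lengths come from exhaustive enumeration of internal-node state
assignments, topology sets from exhaustive edge-insertion, and split
tallies from literal set arithmetic, so they can certify the optimized
implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from morphoclad.matrix import MISSING, CharacterMatrix
from morphoclad.simulate import SimConfig, evolve_matrix, sample_topology
from morphoclad.trees import Tree


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_char_length(tree: Tree, matrix: CharacterMatrix, char: int) -> int:
    """Minimum changes for one character by enumerating every assignment of
    states to internal nodes (missing leaves are free to take any state)."""
    obs = matrix.char_meta[char].observed_states or (0,)
    internal = [n for n in range(tree.n_nodes) if n >= tree.n_leaves]
    leaf_state = {}
    for i, taxon in enumerate(tree.taxa):
        s = matrix.data[matrix.taxon_index(taxon), char]
        leaf_state[i] = None if s == MISSING else int(s)
    edges = tree.edges()
    best = None
    for combo in itertools.product(obs, repeat=len(internal)):
        assign = dict(zip(internal, combo))
        cost = 0
        for u, v in edges:
            su = assign[u] if u in assign else leaf_state[u]
            sv = assign[v] if v in assign else leaf_state[v]
            if su is not None and sv is not None and su != sv:
                cost += 1
        if best is None or cost < best:
            best = cost
    return best


def brute_force_length(tree: Tree, matrix: CharacterMatrix, weights=None) -> float:
    w = np.ones(matrix.n_char) if weights is None else np.asarray(weights, float)
    return float(
        sum(
            w[c] * brute_force_char_length(tree, matrix, c)
            for c in range(matrix.n_char)
        )
    )


def all_topologies(taxa) -> list[Tree]:
    """Every unrooted binary topology over the taxa, by edge insertion."""
    taxa = list(taxa)
    n = len(taxa)
    trees = []

    def build(nbrs, next_id, k):
        if k == n:
            trees.append(Tree(taxa, [list(x) for x in nbrs]))
            return
        edges = [(u, v) for u in range(len(nbrs)) for v in nbrs[u] if u < v]
        for u, v in edges:
            w = next_id
            new = [list(x) for x in nbrs] + [[] for _ in range(next_id + 1 - len(nbrs))]
            new[w] = [u, v, k]
            new[u] = [w if x == v else x for x in new[u]]
            new[v] = [w if x == u else x for x in new[v]]
            new[k] = [w]
            build(new, next_id + 1, k + 1)

    hub = n
    nbrs = [[] for _ in range(n + 1)]
    nbrs[hub] = [0, 1, 2]
    for leaf in range(3):
        nbrs[leaf] = [hub]
    build(nbrs, n + 1, 3)
    return trees


def tbr_neighbors(tree: Tree):
    """Every TBR rearrangement of a binary tree, built by literal cut /
    suppress / resubdivide set operations (independent of the kernels)."""
    out = []
    n = tree.n_leaves
    for u, v in tree.edges():
        a_nodes = _component(tree, u, v)
        b_nodes = set(range(tree.n_nodes)) - a_nodes
        for side, cut, other in ((a_nodes, u, v), ):
            pass
        a_edges = _attach_edges(tree, a_nodes, u)
        b_edges = _attach_edges(tree, b_nodes, v)
        for ae in a_edges or [None]:
            for be in b_edges or [None]:
                t2 = _reconnect(tree, u, v, ae, be)
                if t2 is not None and not t2.same_topology(tree):
                    out.append(t2)
    return out


def _component(tree, u, v):
    seen = {u}
    stack = [u]
    while stack:
        x = stack.pop()
        for y in tree.neighbors(x):
            if y not in seen and not (x == u and y == v):
                seen.add(y)
                stack.append(y)
    return seen


def _attach_edges(tree, nodes, cut):
    if len(nodes) == 1:
        return []
    inner = [
        (x, y)
        for x in nodes
        for y in tree.neighbors(x)
        if y in nodes and x < y and cut not in (x, y)
    ]
    p, q = [x for x in tree.neighbors(cut) if x in nodes]
    return inner + [(min(p, q), max(p, q))]


def _reconnect(tree, u, v, ae, be):
    nbrs = [list(tree.neighbors(i)) for i in range(tree.n_nodes)]

    def replace(node, old, new):
        nbrs[node] = [new if x == old else x for x in nbrs[node]]

    def suppress(cut, keep_nodes):
        p, q = [x for x in nbrs[cut] if x in keep_nodes]
        replace(p, cut, q)
        replace(q, cut, p)

    def subdivide(edge, mid):
        x, y = edge
        replace(x, y, mid)
        replace(y, x, mid)
        return [x, y]

    a_nodes = _component(tree, u, v)
    b_nodes = set(range(tree.n_nodes)) - a_nodes
    if ae is not None:
        suppress(u, a_nodes)
        nbrs[u] = subdivide(ae, u) + [v]
    if be is not None:
        suppress(v, b_nodes)
        nbrs[v] = subdivide(be, v) + [u]
    return Tree(tree.taxa, nbrs)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def random_matrix(seed, n_taxa, n_char, p=0.25, three_state=()):
    """A small simulated matrix (with its truth tree) for oracle tests."""
    rng = np.random.default_rng(seed)
    tree = sample_topology(n_taxa, rng)
    counts = tuple(3 if c in three_state else 2 for c in range(n_char))
    cfg = SimConfig(
        n_taxa=n_taxa, n_char=n_char, state_counts=counts, p=p,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return tree, evolve_matrix(tree, cfg)


@pytest.fixture(scope="session")
def quartet_matrix():
    return CharacterMatrix(list("ABCD"), np.array([[0], [0], [1], [1]]))


@pytest.fixture(scope="session")
def paperlike():
    from morphoclad.simulate import make_paperlike

    return make_paperlike(seed=20260101)
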