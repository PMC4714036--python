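"""Exact most-parsimonious-reconstruction machinery for one character.

Unit-cost Sankoff dynamic programming on a rooted binary tree:

* ``up[x][a]`` — minimal changes within the subtree of ``x`` given state a;
* ``down[x][a]`` — minimal changes everywhere outside the subtree of ``x``
  given ``x`` has state ``a``.

Both passes together give, for every branch, the exact set of
(parent-state, child-state) pairs realized by at least one MPR — the basis
for "unambiguous" change extraction — and the exact set of root states,
and they support full MPR enumeration by independent top-down choices.
"""

from __future__ import annotations

import numpy as np

from .matrix import MISSING, CharacterMatrix
from .trees import RootedTree

INF = 10**9


class CharDP:
    """Unit-cost ancestral-state DP for a single character."""

    def __init__(self, rtree: RootedTree, leaf_states: dict[int, frozenset[int]], k: int):
        """``leaf_states`` maps leaf id -> allowed (compact) states; ``k``
        is the number of observed states (missing leaves allow all)."""
        self.rtree = rtree
        self.k = max(k, 1)
        n = rtree.n_nodes
        self.up = np.full((n, self.k), INF, dtype=np.int64)
        for node in rtree.postorder:
            if rtree.is_leaf(node):
                allowed = leaf_states.get(node, frozenset(range(self.k)))
                for a in allowed:
                    self.up[node, a] = 0
            else:
                for a in range(self.k):
                    tot = 0
                    for ch in rtree.children[node]:
                        tot += min(
                            self.up[ch, b] + (1 if a != b else 0)
                            for b in range(self.k)
                        )
                    self.up[node, a] = tot
        self.min_length = int(self.up[rtree.root].min())
        # downward pass
        self.down = np.full((n, self.k), INF, dtype=np.int64)
        self.down[rtree.root, :] = 0
        self._env: dict[int, np.ndarray] = {}
        for node in rtree.preorder:
            if rtree.is_leaf(node):
                continue
            for ch in rtree.children[node]:
                sib_cost = np.zeros(self.k, dtype=np.int64)
                for b in range(self.k):
                    tot = self.down[node, b]
                    for other in rtree.children[node]:
                        if other != ch:
                            tot += min(
                                self.up[other, c] + (1 if b != c else 0)
                                for c in range(self.k)
                            )
                    sib_cost[b] = tot
                for a in range(self.k):
                    self.down[ch, a] = min(
                        sib_cost[b] + (1 if a != b else 0) for b in range(self.k)
                    )
                # parent-side envelope cached for pair queries
                self._env[ch] = sib_cost

    def root_states(self) -> frozenset[int]:
        u = self.up[self.rtree.root]
        return frozenset(int(a) for a in range(self.k) if u[a] == self.min_length)

    def edge_pairs(self, child: int) -> frozenset[tuple[int, int]]:
        """All (parent_state, child_state) pairs realized by some MPR on the
        branch above ``child``."""
        env = self._env[child]
        best = INF
        pairs = []
        for b in range(self.k):
            for a in range(self.k):
                cost = env[b] + (1 if a != b else 0) + self.up[child, a]
                if cost < best:
                    best = cost
                    pairs = [(b, a)]
                elif cost == best:
                    pairs.append((b, a))
        assert best == self.min_length
        return frozenset(pairs)

    def edge_min_changes(self, child: int) -> int:
        """Minimum changes on the branch above ``child`` over all MPRs."""
        return 0 if any(a == b for b, a in self.edge_pairs(child)) else 1

    def optimal_child_states(self, child: int, parent_state: int) -> list[int]:
        u = self.up[child]
        costs = [u[a] + (1 if a != parent_state else 0) for a in range(self.k)]
        best = min(costs)
        return [a for a in range(self.k) if costs[a] == best]

    # -- reconstructions -------------------------------------------------

    def enumerate(self, cap: int = 100000) -> list[dict[int, int]]:
        """All MPRs as node -> state maps (cap guards pathological blowup)."""
        rtree = self.rtree
        out: list[dict[int, int]] = []
        partial: dict[int, int] = {}

        def rec(idx: int) -> bool:
            if len(out) >= cap:
                return False
            if idx == len(rtree.preorder):
                out.append(dict(partial))
                return True
            node = rtree.preorder[idx]
            if node == rtree.root:
                choices = sorted(self.root_states())
            else:
                choices = self.optimal_child_states(node, partial[rtree.parent[node]])
            for a in choices:
                partial[node] = a
                if not rec(idx + 1):
                    return False
            return True

        complete = rec(0)
        if not complete:
            raise RuntimeError(f"MPR enumeration exceeded cap={cap}")
        return out

    def greedy(self, accelerate: bool) -> dict[int, int]:
        """One MPR chosen top-down.

        ``accelerate=False`` (DELTRAN-style) keeps the parent state
        whenever optimal, delaying changes; ``accelerate=True``
        (ACCTRAN-style) switches to a differing optimal state when one
        exists, placing changes as close to the root as possible.  Ties
        break to the smallest state index.
        """
        rtree = self.rtree
        assign: dict[int, int] = {}
        for node in rtree.preorder:
            if node == rtree.root:
                assign[node] = min(self.root_states())
                continue
            ps = assign[rtree.parent[node]]
            opts = self.optimal_child_states(node, ps)
            if accelerate:
                diff = [a for a in opts if a != ps]
                assign[node] = diff[0] if diff else opts[0]
            else:
                assign[node] = ps if ps in opts else opts[0]
        return assign


def character_dp(rtree: RootedTree, matrix: CharacterMatrix, char: int) -> CharDP:
    """Build the DP for one matrix character on a rooted tree.

    Leaf ids in ``rtree`` index ``rtree.taxa``; matrix states are remapped
    to compact 0..k-1 in observed-state order (the inverse map is exposed
    as ``dp.state_of``/``dp.code_of``).
    """
    obs = matrix.char_meta[char].observed_states
    k = max(len(obs), 1)
    code = {s: i for i, s in enumerate(obs)}
    leaf_states: dict[int, frozenset[int]] = {}
    for i, taxon in enumerate(rtree.taxa):
        s = matrix.data[matrix.taxon_index(taxon), char]
        if s != MISSING:
            leaf_states[i] = frozenset([code[int(s)]])
    dp = CharDP(rtree, leaf_states, k)
    dp.state_of = dict(enumerate(obs)) if obs else {0: 0}
    dp.code_of = code
    return dp
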