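"""Unrooted and rooted tree topologies over taxon labels.

Trees are stored as adjacency lists over integer node ids; leaves
``0..n-1`` correspond to the taxon tuple in order, internal nodes follow.
Unrooted trees are the currency of parsimony search; rooting (on an
outgroup edge) is required only for ancestral-state mapping, where change
polarity matters.

Newick text is parsed through dendropy; writing (including the canonical
sorted form used for topology identity and deterministic tie-breaking) is
done directly, since the canonical form is not a dendropy concept.
"""

from __future__ import annotations

from functools import cached_property

import numpy as np


class TreeError(ValueError):
    pass


class Tree:
    """An unrooted tree (binary or multifurcating) over a fixed taxon set."""

    def __init__(self, taxa, nbrs):
        self.taxa: tuple[str, ...] = tuple(taxa)
        self._nbrs: list[list[int]] = [sorted(x) for x in nbrs]
        n = len(self.taxa)
        if n < 3:
            raise TreeError("need at least 3 taxa for an unrooted tree")
        for leaf in range(n):
            if len(self._nbrs[leaf]) != 1:
                raise TreeError(f"leaf node {leaf} has degree {len(self._nbrs[leaf])}")

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_kernel(cls, nbr: np.ndarray, taxa) -> "Tree":
        """Build from the fixed-width (2n-2, 3) array used by search kernels."""
        nbrs = [[int(x) for x in row if x >= 0] for row in nbr]
        return cls(taxa, nbrs)

    @classmethod
    def from_newick(cls, text: str, taxa=None) -> "Tree":
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick")
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if taxa is None:
            taxa = sorted(labels)
        if set(labels) != set(taxa):
            raise TreeError("newick leaf labels do not match the given taxon set")
        index = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        nbrs: list[list[int]] = [[] for _ in range(n)]
        ids: dict = {}
        next_id = n

        def node_id(nd):
            nonlocal next_id
            if nd.is_leaf():
                return index[nd.taxon.label]
            if nd not in ids:
                ids[nd] = next_id
                nbrs.append([])
                next_id += 1
            return ids[nd]

        for nd in dtree.preorder_node_iter():
            for ch in nd.child_nodes():
                a, b = node_id(nd), node_id(ch)
                nbrs[a].append(b)
                nbrs[b].append(a)
        tree = cls(taxa, nbrs)
        # a bifurcating "root" is an artifact of rooted newick: suppress it
        root_id = node_id(dtree.seed_node)
        if len(tree._nbrs[root_id]) == 2:
            tree = tree._suppress_degree2(root_id)
        return tree

    def _suppress_degree2(self, node: int) -> "Tree":
        a, b = self._nbrs[node]
        nbrs = [list(x) for x in self._nbrs]
        nbrs[a] = [b if x == node else x for x in nbrs[a]]
        nbrs[b] = [a if x == node else x for x in nbrs[b]]
        nbrs[node] = []
        # compact ids: drop the removed node
        keep = [i for i in range(len(nbrs)) if i != node]
        remap = {old: new for new, old in enumerate(keep)}
        new_nbrs = [[remap[x] for x in nbrs[old]] for old in keep]
        return Tree(self.taxa, new_nbrs)

    # -- basic structure -------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self._nbrs)

    def neighbors(self, node: int) -> list[int]:
        return list(self._nbrs[node])

    def degree(self, node: int) -> int:
        return len(self._nbrs[node])

    @property
    def is_binary(self) -> bool:
        return all(
            len(nb) in (1, 3) for nb in self._nbrs
        ) and self.n_nodes == 2 * self.n_leaves - 2

    def edges(self):
        """All edges as (u, v) with u < v."""
        return [
            (u, v) for u in range(self.n_nodes) for v in self._nbrs[u] if u < v
        ]

    def leaves_behind(self, parent: int, child: int) -> frozenset[int]:
        """Leaf ids in the component containing ``child`` when edge is cut."""
        seen = {parent, child}
        stack = [child]
        leaves = set()
        while stack:
            x = stack.pop()
            if x < self.n_leaves:
                leaves.add(x)
            for y in self._nbrs[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(leaves)

    # -- topology identity ----------------------------------------------

    @cached_property
    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Nontrivial splits, each as the taxon set on the side away from taxa[0]."""
        out = set()
        n = self.n_leaves
        for u, v in self.edges():
            side = self.leaves_behind(u, v)
            if 0 in side:
                side = frozenset(range(n)) - side
            if 2 <= len(side) <= n - 2:
                out.add(frozenset(self.taxa[i] for i in side))
        return frozenset(out)

    def same_topology(self, other: "Tree") -> bool:
        return set(self.taxa) == set(other.taxa) and self.bipartitions == other.bipartitions

    # -- newick ----------------------------------------------------------

    def _subtree_newick(self, node: int, parent: int, canonical: bool, labels=None) -> str:
        if node < self.n_leaves:
            return self.taxa[node].replace(" ", "_")
        parts = [
            self._subtree_newick(ch, node, canonical, labels)
            for ch in self._nbrs[node]
            if ch != parent
        ]
        if canonical:
            parts.sort()
        lab = "" if labels is None else labels.get(node, "")
        return "(" + ",".join(parts) + ")" + lab

    def to_newick(self, canonical: bool = False, labels=None) -> str:
        """Unrooted newick with a basal multifurcation at taxa[0]'s neighbor."""
        hub = self._nbrs[0][0]
        parts = [self.taxa[0].replace(" ", "_")] + [
            self._subtree_newick(ch, hub, canonical, labels)
            for ch in self._nbrs[hub]
            if ch != 0
        ]
        if canonical:
            parts = [parts[0]] + sorted(parts[1:])
        return "(" + ",".join(parts) + ");"

    @cached_property
    def canonical_newick(self) -> str:
        return self.to_newick(canonical=True)

    def __repr__(self) -> str:
        return f"Tree({self.n_leaves} leaves)"

    # -- kernel interop --------------------------------------------------

    def to_kernel(self) -> np.ndarray:
        if not self.is_binary:
            raise TreeError("kernel representation requires a binary unrooted tree")
        nbr = np.full((self.n_nodes, 3), -1, dtype=np.int32)
        for i, nb in enumerate(self._nbrs):
            nbr[i, : len(nb)] = nb
        return nbr

    # -- editing ---------------------------------------------------------

    def collapse_edges(self, internal_edges) -> "Tree":
        """Collapse the given internal edges, producing a multifurcating tree."""
        parent_of = {}
        merged = {i: i for i in range(self.n_nodes)}

        def find(x):
            while merged[x] != x:
                merged[x] = merged[merged[x]]
                x = merged[x]
            return x

        for u, v in internal_edges:
            if u < self.n_leaves or v < self.n_leaves:
                raise TreeError("only internal edges can be collapsed")
            ru, rv = find(u), find(v)
            if ru != rv:
                merged[max(ru, rv)] = min(ru, rv)
        groups: dict[int, int] = {}
        new_nbrs: list[list[int]] = [[] for _ in range(self.n_leaves)]
        next_id = self.n_leaves
        for node in range(self.n_nodes):
            root = find(node)
            if root >= self.n_leaves and root not in groups:
                groups[root] = next_id
                new_nbrs.append([])
                next_id += 1

        def new_id(x):
            r = find(x)
            return r if r < self.n_leaves else groups[r]

        seen = set()
        for u, v in self.edges():
            a, b = new_id(u), new_id(v)
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            new_nbrs[a].append(b)
            new_nbrs[b].append(a)
        return Tree(self.taxa, new_nbrs)

    # -- rooting ---------------------------------------------------------

    def root_on_edge(self, u: int, v: int) -> "RootedTree":
        """Root by subdividing edge (u, v) with a new root node."""
        if v not in self._nbrs[u]:
            raise TreeError(f"({u}, {v}) is not an edge")
        return RootedTree._from_unrooted(self, u, v)

    def root_with_outgroups(self, outgroup_taxa) -> "RootedTree":
        """Root on the edge separating the outgroups from the ingroup.

        If the outgroup set is not a split of the tree, fall back to the
        pendant edge of the first outgroup taxon.
        """
        og = [t for t in outgroup_taxa if t in self.taxa]
        if not og:
            raise TreeError("no outgroup taxa present in the tree")
        og_ids = {self.taxa.index(t) for t in og}
        if len(og_ids) > 1:
            for u, v in self.edges():
                if self.leaves_behind(u, v) == frozenset(og_ids):
                    return self.root_on_edge(u, v)
        leaf = min(og_ids)
        return self.root_on_edge(self._nbrs[leaf][0], leaf)


class RootedTree:
    """A rooted view of an unrooted tree, for ancestral-state mapping."""

    def __init__(self, taxa, children, parent, root):
        self.taxa = tuple(taxa)
        self.children: list[list[int]] = children
        self.parent: list[int] = parent
        self.root: int = root

    @classmethod
    def _from_unrooted(cls, tree: Tree, u: int, v: int) -> "RootedTree":
        root = tree.n_nodes
        children: list[list[int]] = [[] for _ in range(root + 1)]
        parent = [-1] * (root + 1)
        children[root] = [u, v]
        parent[u] = parent[v] = root
        stack = [u, v]
        while stack:
            node = stack.pop()
            for nb in tree._nbrs[node]:
                if nb != parent[node] and not (
                    {node, nb} == {u, v}
                ):
                    children[node].append(nb)
                    parent[nb] = node
                    stack.append(nb)
        return cls(tree.taxa, children, parent, root)

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    def is_leaf(self, node: int) -> bool:
        return node < self.n_leaves

    @cached_property
    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    @cached_property
    def preorder(self) -> list[int]:
        return list(reversed(self.postorder))

    @cached_property
    def leafset(self) -> dict[int, frozenset[int]]:
        out: dict[int, frozenset[int]] = {}
        for node in self.postorder:
            if self.is_leaf(node):
                out[node] = frozenset([node])
            else:
                s: frozenset[int] = frozenset()
                for ch in self.children[node]:
                    s |= out[ch]
                out[node] = s
        return out

    def ancestors(self, node: int) -> list[int]:
        """Strict ancestors, nearest first."""
        out = []
        p = self.parent[node]
        while p != -1:
            out.append(p)
            p = self.parent[p]
        return out

    def mrca(self, leaf_ids) -> int:
        target = frozenset(leaf_ids)
        best = self.root
        for node in self.postorder:
            if target <= self.leafset[node] and self.leafset[node] < self.leafset[best]:
                best = node
        return best

    def to_newick(self, labels=None) -> str:
        def rec(node):
            lab = "" if labels is None else labels.get(node, "")
            if self.is_leaf(node):
                return self.taxa[node].replace(" ", "_") + lab
            parts = [rec(ch) for ch in self.children[node]]
            return "(" + ",".join(parts) + ")" + lab

        return rec(self.root) + ";"
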