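"""JIT-compiled kernels for parsimony scoring and branch swapping.

Trees enter these kernels as a fixed-width adjacency array ``nbr`` of
shape ``(n_nodes, 3)``: row ``i`` lists the neighbors of node ``i`` and is
padded with ``-1``.  Leaves are ids ``0..n_leaves-1`` (n_leaves =
``leaf_masks.shape[0]``), internal nodes follow.  Character states are
bitmasks (uint8), so unordered Fitch optimization is intersection/union
per character; a missing cell carries the full observed-state mask and
therefore never forces a change.

Rows of inactive nodes (all ``-1``) are permitted: traversal starts from a
given leaf and visits only its component, which is what stepwise addition
needs for partial trees.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True)
def _traverse(nbr, start_leaf, order, parent):
    """Preorder from ``start_leaf``; fills order/parent, returns node count."""
    n_nodes = nbr.shape[0]
    for i in range(n_nodes):
        parent[i] = -2
    stack = np.empty(n_nodes, np.int32)
    parent[start_leaf] = -1
    hub = nbr[start_leaf, 0]
    parent[hub] = start_leaf
    top = 0
    stack[0] = hub
    order[0] = start_leaf
    cnt = 1
    while top >= 0:
        node = stack[top]
        top -= 1
        order[cnt] = node
        cnt += 1
        for j in range(3):
            x = nbr[node, j]
            if x >= 0 and x != parent[node]:
                parent[x] = node
                top += 1
                stack[top] = x
    return cnt


@nb.njit(cache=True)
def fitch_wlen(nbr, leaf_masks, weights, start_leaf):
    """Weighted Fitch length of the (possibly partial) tree containing start_leaf."""
    n_nodes = nbr.shape[0]
    n_leaves = leaf_masks.shape[0]
    n_char = leaf_masks.shape[1]
    order = np.empty(n_nodes, np.int32)
    parent = np.empty(n_nodes, np.int32)
    cnt = _traverse(nbr, start_leaf, order, parent)
    masks = np.empty((n_nodes, n_char), np.uint8)
    total = 0.0
    for k in range(cnt - 1, 0, -1):
        node = order[k]
        if node < n_leaves:
            for c in range(n_char):
                masks[node, c] = leaf_masks[node, c]
        else:
            c1 = np.int32(-1)
            c2 = np.int32(-1)
            for j in range(3):
                x = nbr[node, j]
                if x >= 0 and x != parent[node]:
                    if c1 < 0:
                        c1 = x
                    else:
                        c2 = x
            for c in range(n_char):
                inter = masks[c1, c] & masks[c2, c]
                if inter == 0:
                    masks[node, c] = masks[c1, c] | masks[c2, c]
                    total += weights[c]
                else:
                    masks[node, c] = inter
    hub = nbr[start_leaf, 0]
    for c in range(n_char):
        if leaf_masks[start_leaf, c] & masks[hub, c] == 0:
            total += weights[c]
    return total


@nb.njit(cache=True)
def fitch_steps(nbr, leaf_masks, start_leaf, steps):
    """Per-character Fitch step counts; ``steps`` is an int64 output array."""
    n_nodes = nbr.shape[0]
    n_leaves = leaf_masks.shape[0]
    n_char = leaf_masks.shape[1]
    order = np.empty(n_nodes, np.int32)
    parent = np.empty(n_nodes, np.int32)
    cnt = _traverse(nbr, start_leaf, order, parent)
    masks = np.empty((n_nodes, n_char), np.uint8)
    for c in range(n_char):
        steps[c] = 0
    for k in range(cnt - 1, 0, -1):
        node = order[k]
        if node < n_leaves:
            for c in range(n_char):
                masks[node, c] = leaf_masks[node, c]
        else:
            c1 = np.int32(-1)
            c2 = np.int32(-1)
            for j in range(3):
                x = nbr[node, j]
                if x >= 0 and x != parent[node]:
                    if c1 < 0:
                        c1 = x
                    else:
                        c2 = x
            for c in range(n_char):
                inter = masks[c1, c] & masks[c2, c]
                if inter == 0:
                    masks[node, c] = masks[c1, c] | masks[c2, c]
                    steps[c] += 1
                else:
                    masks[node, c] = inter
    hub = nbr[start_leaf, 0]
    for c in range(n_char):
        if leaf_masks[start_leaf, c] & masks[hub, c] == 0:
            steps[c] += 1


@nb.njit(cache=True)
def _replace(nbr, node, old, new):
    for j in range(3):
        if nbr[node, j] == old:
            nbr[node, j] = new
            return


@nb.njit(cache=True)
def _component(nbr, u, v, comp):
    """comp[x] = 1 for nodes on u's side when edge (u, v) is cut, else 0."""
    n_nodes = nbr.shape[0]
    for i in range(n_nodes):
        comp[i] = 0
    stack = np.empty(n_nodes, np.int32)
    top = 0
    stack[0] = u
    comp[u] = 1
    while top >= 0:
        node = stack[top]
        top -= 1
        for j in range(3):
            x = nbr[node, j]
            if x >= 0 and comp[x] == 0 and not (node == u and x == v):
                comp[x] = 1
                top += 1
                stack[top] = x
    return comp


@nb.njit(cache=True)
def _side_edges(nbr, cut_node, side_val, comp, e1, e2):
    """Attachment edges on one side: edges within the side not incident to
    cut_node, plus (as the LAST entry) the edge formed by suppressing
    cut_node.  Returns (count, has_suppressed)."""
    n_nodes = nbr.shape[0]
    cnt = 0
    for x in range(n_nodes):
        if comp[x] != side_val or x == cut_node:
            continue
        for j in range(3):
            y = nbr[x, j]
            if y < 0 or y <= x or comp[y] != side_val or y == cut_node:
                continue
            e1[cnt] = x
            e2[cnt] = y
            cnt += 1
    # suppressed pair: cut_node's neighbors within the side
    p = np.int32(-1)
    q = np.int32(-1)
    for j in range(3):
        x = nbr[cut_node, j]
        if x >= 0 and comp[x] == side_val:
            if p < 0:
                p = x
            else:
                q = x
    if q >= 0:
        e1[cnt] = p
        e2[cnt] = q
        cnt += 1
        return cnt, True
    return cnt, False


@nb.njit(cache=True)
def _build_tbr(nbr, cand, u, v, a1, a2, b1, b2, p, q, r, s):
    """Write the TBR neighbor into ``cand``.

    a1 < 0 means side A is a single leaf (u); b1 < 0 likewise for v.
    (p, q) / (r, s) are the suppressed-neighbor pairs of u / v (q or s is
    -1 when the corresponding side is trivial)."""
    for i in range(nbr.shape[0]):
        for j in range(3):
            cand[i, j] = nbr[i, j]
    if a1 >= 0:
        _replace(cand, p, u, q)
        _replace(cand, q, u, p)
    if b1 >= 0:
        _replace(cand, r, v, s)
        _replace(cand, s, v, r)
    if a1 >= 0:
        cand[u, 0] = a1
        cand[u, 1] = a2
        cand[u, 2] = v
        _replace(cand, a1, a2, u)
        _replace(cand, a2, a1, u)
    if b1 >= 0:
        cand[v, 0] = b1
        cand[v, 1] = b2
        cand[v, 2] = u
        _replace(cand, b1, b2, v)
        _replace(cand, b2, b1, v)


@nb.njit(cache=True)
def _suppressed_pair(nbr, cut_node, comp, side_val):
    p = np.int32(-1)
    q = np.int32(-1)
    for j in range(3):
        x = nbr[cut_node, j]
        if x >= 0 and comp[x] == side_val:
            if p < 0:
                p = x
            else:
                q = x
    return p, q


@nb.njit(cache=True)
def tbr_pass(nbr, leaf_masks, weights, cur_len, steepest):
    """One sweep over the TBR neighborhood.

    With ``steepest`` false, the first strictly improving rearrangement is
    applied to ``nbr`` in place and its length returned; with ``steepest``
    true the whole neighborhood is scanned and the best improvement
    applied.  Returns the (possibly unchanged) length.
    """
    n_nodes = nbr.shape[0]
    n_leaves = leaf_masks.shape[0]
    comp = np.empty(n_nodes, np.uint8)
    cand = np.empty_like(nbr)
    best = np.empty_like(nbr)
    ae1 = np.empty(n_nodes, np.int32)
    ae2 = np.empty(n_nodes, np.int32)
    be1 = np.empty(n_nodes, np.int32)
    be2 = np.empty(n_nodes, np.int32)
    best_len = cur_len
    improved = False
    eps = 1e-9
    for u in range(n_nodes):
        for j in range(3):
            v = nbr[u, j]
            if v < 0 or v < u:
                continue
            _component(nbr, u, v, comp)
            a_leaf = u < n_leaves
            b_leaf = v < n_leaves
            p, q = _suppressed_pair(nbr, u, comp, 1)
            r, s = _suppressed_pair(nbr, v, comp, 0)
            if a_leaf:
                na = 1
            else:
                na, _ = _side_edges(nbr, u, 1, comp, ae1, ae2)
            if b_leaf:
                nbv = 1
            else:
                nbv, _ = _side_edges(nbr, v, 0, comp, be1, be2)
            for ia in range(na):
                if a_leaf:
                    a1 = np.int32(-1)
                    a2 = np.int32(-1)
                else:
                    a1 = ae1[ia]
                    a2 = ae2[ia]
                a_is_orig = a_leaf or (
                    (a1 == p and a2 == q) or (a1 == q and a2 == p)
                )
                for ib in range(nbv):
                    if b_leaf:
                        b1 = np.int32(-1)
                        b2 = np.int32(-1)
                    else:
                        b1 = be1[ib]
                        b2 = be2[ib]
                    b_is_orig = b_leaf or (
                        (b1 == r and b2 == s) or (b1 == s and b2 == r)
                    )
                    if a_is_orig and b_is_orig:
                        continue  # regenerates the current tree
                    _build_tbr(nbr, cand, u, v, a1, a2, b1, b2, p, q, r, s)
                    L = fitch_wlen(cand, leaf_masks, weights, 0)
                    if L < best_len - eps:
                        if not steepest:
                            for x in range(n_nodes):
                                for y in range(3):
                                    nbr[x, y] = cand[x, y]
                            return L
                        best_len = L
                        improved = True
                        for x in range(n_nodes):
                            for y in range(3):
                                best[x, y] = cand[x, y]
    if improved:
        for x in range(n_nodes):
            for y in range(3):
                nbr[x, y] = best[x, y]
    return best_len


@nb.njit(cache=True)
def tbr_equal_neighbors(nbr, leaf_masks, weights, target_len, out):
    """Collect TBR neighbors whose length equals ``target_len``.

    ``out`` has shape (cap, n_nodes, 3); returns the number stored
    (duplicates possible — the caller deduplicates by topology).
    """
    n_nodes = nbr.shape[0]
    n_leaves = leaf_masks.shape[0]
    cap = out.shape[0]
    comp = np.empty(n_nodes, np.uint8)
    cand = np.empty_like(nbr)
    ae1 = np.empty(n_nodes, np.int32)
    ae2 = np.empty(n_nodes, np.int32)
    be1 = np.empty(n_nodes, np.int32)
    be2 = np.empty(n_nodes, np.int32)
    cnt = 0
    eps = 1e-9
    for u in range(n_nodes):
        for j in range(3):
            v = nbr[u, j]
            if v < 0 or v < u:
                continue
            _component(nbr, u, v, comp)
            a_leaf = u < n_leaves
            b_leaf = v < n_leaves
            p, q = _suppressed_pair(nbr, u, comp, 1)
            r, s = _suppressed_pair(nbr, v, comp, 0)
            if a_leaf:
                na = 1
            else:
                na, _ = _side_edges(nbr, u, 1, comp, ae1, ae2)
            if b_leaf:
                nbv = 1
            else:
                nbv, _ = _side_edges(nbr, v, 0, comp, be1, be2)
            for ia in range(na):
                if a_leaf:
                    a1 = np.int32(-1)
                    a2 = np.int32(-1)
                else:
                    a1 = ae1[ia]
                    a2 = ae2[ia]
                a_is_orig = a_leaf or (
                    (a1 == p and a2 == q) or (a1 == q and a2 == p)
                )
                for ib in range(nbv):
                    if b_leaf:
                        b1 = np.int32(-1)
                        b2 = np.int32(-1)
                    else:
                        b1 = be1[ib]
                        b2 = be2[ib]
                    b_is_orig = b_leaf or (
                        (b1 == r and b2 == s) or (b1 == s and b2 == r)
                    )
                    if a_is_orig and b_is_orig:
                        continue
                    _build_tbr(nbr, cand, u, v, a1, a2, b1, b2, p, q, r, s)
                    L = fitch_wlen(cand, leaf_masks, weights, 0)
                    if abs(L - target_len) <= eps:
                        for x in range(n_nodes):
                            for y in range(3):
                                out[cnt, x, y] = cand[x, y]
                        cnt += 1
                        if cnt == cap:
                            return cnt
    return cnt


@nb.njit(cache=True)
def greedy_stepwise(order, leaf_masks, weights):
    """Stepwise addition holding a single tree (hold=1), ties to the first edge.

    ``order`` is a permutation of all leaf ids; returns the full adjacency.
    """
    n_leaves = leaf_masks.shape[0]
    n_nodes = 2 * n_leaves - 2
    nbr = np.full((n_nodes, 3), -1, np.int32)
    o0, o1, o2 = order[0], order[1], order[2]
    hub = n_leaves
    nbr[hub, 0] = o0
    nbr[hub, 1] = o1
    nbr[hub, 2] = o2
    nbr[o0, 0] = hub
    nbr[o1, 0] = hub
    nbr[o2, 0] = hub
    next_internal = n_leaves + 1
    for k in range(3, n_leaves):
        leaf = order[k]
        w = next_internal
        best_len = np.inf
        bx = np.int32(-1)
        by = np.int32(-1)
        for x in range(n_nodes):
            for j in range(3):
                y = nbr[x, j]
                if y < 0 or y < x:
                    continue
                # insert leaf on edge (x, y) via new node w
                nbr[w, 0] = x
                nbr[w, 1] = y
                nbr[w, 2] = leaf
                _replace(nbr, x, y, w)
                _replace(nbr, y, x, w)
                nbr[leaf, 0] = w
                L = fitch_wlen(nbr, leaf_masks, weights, o0)
                # revert
                _replace(nbr, x, w, y)
                _replace(nbr, y, w, x)
                nbr[w, 0] = -1
                nbr[w, 1] = -1
                nbr[w, 2] = -1
                nbr[leaf, 0] = -1
                if L < best_len - 1e-9:
                    best_len = L
                    bx = x
                    by = y
        nbr[w, 0] = bx
        nbr[w, 1] = by
        nbr[w, 2] = leaf
        _replace(nbr, bx, by, w)
        _replace(nbr, by, bx, w)
        nbr[leaf, 0] = w
        next_internal += 1
    return nbr
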