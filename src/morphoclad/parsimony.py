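"""Parsimony scoring: weighted Fitch length, step bounds, and fit indices.

For an unordered character ``i`` on a binary unrooted tree, the observed
steps ``s_i`` are the minimum number of state changes (Fitch 1971, via the
bitmask kernels).  The conceivable bounds are

* ``m_i`` — observed states among scored taxa minus one (best case), and
* ``g_i`` — scored taxa minus the count of the most frequent state (worst
  case, attained on a star/bush).

From these the standard ensemble fit measures follow: consistency index
``CI = Σm/Σs``, homoplasy index ``HI = 1 − CI``, retention index
``RI = (Σg − Σs)/(Σg − Σm)`` and rescaled consistency ``RC = CI·RI``.
Under non-unit character weights all sums are weighted, which is how the
successive-weighting statistics are conventionally reported.

Uninformative (invariant and autapomorphic) characters are *included* in
the ensemble sums; they contribute equally to Σm and Σs and so inflate CI
the same way the classic PAUP report does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .matrix import MISSING, CharacterMatrix
from .trees import Tree


class ScoringError(ValueError):
    pass


def unit_weights(n_char: int) -> np.ndarray:
    """The equal-weighting vector (all ones)."""
    return np.ones(n_char, dtype=np.float64)


def as_weights(weights, n_char: int) -> np.ndarray:
    """Validate/coerce a weight vector; None means equal weights."""
    if weights is None:
        return unit_weights(n_char)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (n_char,):
        raise ScoringError(f"weight vector length {w.shape} != n_char {n_char}")
    if (w < 0).any():
        raise ScoringError("negative character weight")
    return w


def leaf_masks_for(matrix: CharacterMatrix, taxa_order) -> np.ndarray:
    """Per-(leaf, character) state bitmasks aligned to ``taxa_order``.

    States are remapped per character to bit positions in observed-state
    order; a missing cell gets the full observed mask (so it can never
    force a change), and an all-missing character gets a single dummy
    state, making it cost-free everywhere.
    """
    rows = [matrix.taxon_index(t) for t in taxa_order]
    n_char = matrix.n_char
    masks = np.zeros((len(rows), n_char), dtype=np.uint8)
    for c in range(n_char):
        obs = matrix.char_meta[c].observed_states
        if len(obs) > 8:
            raise ScoringError(f"character {c + 1} has {len(obs)} states (max 8)")
        bit = {s: 1 << k for k, s in enumerate(obs)}
        full = (1 << max(len(obs), 1)) - 1
        for i, r in enumerate(rows):
            s = int(matrix.data[r, c])
            masks[i, c] = full if s == MISSING else bit[s]
    return masks


def _check_tree(tree: Tree, matrix: CharacterMatrix) -> None:
    ts, ms = set(tree.taxa), set(matrix.taxa)
    if ts != ms:
        diff = sorted(ts.symmetric_difference(ms))
        raise ScoringError(f"tree/matrix taxon mismatch: {diff}")
    if not tree.is_binary:
        raise ScoringError("scoring requires a binary tree (polytomies refused)")


def per_character_steps(tree: Tree, matrix: CharacterMatrix) -> np.ndarray:
    """Fitch step counts s_i for every character on ``tree``."""
    _check_tree(tree, matrix)
    masks = leaf_masks_for(matrix, tree.taxa)
    steps = np.zeros(matrix.n_char, dtype=np.int64)
    _kernels.fitch_steps(tree.to_kernel(), masks, 0, steps)
    return steps


def tree_length(tree: Tree, matrix: CharacterMatrix, weights=None):
    """Weighted tree length L = Σ w_i·s_i and the per-character steps."""
    w = as_weights(weights, matrix.n_char)
    steps = per_character_steps(tree, matrix)
    return float(np.dot(w, steps)), steps


def char_bounds(matrix: CharacterMatrix):
    """Minimum (m_i) and maximum (g_i) conceivable steps per character.

    Counts use scored (non-missing) taxa only; characters with fewer than
    two observed states get m = g = 0.
    """
    m = np.zeros(matrix.n_char, dtype=np.int64)
    g = np.zeros(matrix.n_char, dtype=np.int64)
    for c in range(matrix.n_char):
        col = matrix.data[:, c]
        scored = col[col != MISSING]
        states, counts = np.unique(scored, return_counts=True)
        if len(states) < 2:
            continue
        m[c] = len(states) - 1
        g[c] = scored.size - counts.max()
    return m, g


@dataclass(frozen=True)
class FitProfile:
    """Per-character steps/bounds/indices and the ensemble fit measures."""

    s: np.ndarray
    m: np.ndarray
    g: np.ndarray
    weights: np.ndarray
    L: float
    CI: float
    HI: float
    RI: float
    RC: float
    ci: list = field(repr=False, default_factory=list)
    ri: list = field(repr=False, default_factory=list)
    rc: list = field(repr=False, default_factory=list)

    def to_table(self):
        """Per-character table (pandas DataFrame, 1-based character ids)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "char": np.arange(1, len(self.s) + 1),
                "weight": self.weights,
                "steps": self.s,
                "min_steps": self.m,
                "max_steps": self.g,
                "ci": self.ci,
                "ri": self.ri,
                "rc": self.rc,
            }
        )


def fit_indices(tree, matrix: CharacterMatrix, weights=None) -> FitProfile:
    """Fit profile for a tree (or the best tree of a tree set).

    When an iterable of trees is given, each is scored and the profile of
    the shortest (ties: the first) is returned.
    """
    if isinstance(tree, Tree):
        trees = [tree]
    else:
        trees = list(tree)
        if not trees:
            raise ScoringError("empty tree set")
    w = as_weights(weights, matrix.n_char)
    best = None
    for t in trees:
        L, steps = tree_length(t, matrix, w)
        if best is None or L < best[0] - 1e-12:
            best = (L, steps)
    L, s = best
    m, g = char_bounds(matrix)
    ci = [float(m[i]) / s[i] if s[i] > 0 else None for i in range(len(s))]
    ri = [
        float(g[i] - s[i]) / (g[i] - m[i]) if s[i] > 0 and g[i] > m[i] else None
        for i in range(len(s))
    ]
    rc = [
        (ci[i] * ri[i]) if (ci[i] is not None and ri[i] is not None) else None
        for i in range(len(s))
    ]
    ws, wm, wg = float(np.dot(w, s)), float(np.dot(w, m)), float(np.dot(w, g))
    CI = wm / ws if ws > 0 else 1.0
    RI = (wg - ws) / (wg - wm) if wg > wm else 1.0
    RC = CI * RI
    return FitProfile(
        s=s, m=m, g=g, weights=w, L=L, CI=CI, HI=1.0 - CI, RI=RI, RC=RC,
        ci=ci, ri=ri, rc=rc,
    )
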