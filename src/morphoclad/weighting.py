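"""Successive-approximations character weighting.

Characters are reweighted by their own fit (by default the rescaled
consistency index, best value over the current most-parsimonious trees),
the search is repeated under the new weights, and the cycle iterates
until the tree set stabilizes.  Weights live in [0, 1]; a homoplasy-free
character keeps weight 1, a maximally homoplastic one approaches 0, so
the procedure progressively concentrates the analysis on the characters
that are consistent on the emerging topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix
from .parsimony import as_weights, char_bounds, per_character_steps, fit_indices
from .search import SearchConfig, SearchResult, heuristic_search


class WeightingError(ValueError):
    pass


def _char_index(s: int, m: int, g: int, basis: str) -> float:
    """Per-character fit index used as a weight; see module docstring.

    Characters that cannot show homoplasy (invariant: s = 0; or no worse
    tree exists: g = m) count as perfectly consistent (index 1), never 0.
    """
    if s == 0:
        return 1.0
    ci = m / s
    if basis == "ci":
        return ci
    ri = (g - s) / (g - m) if g > m else 1.0
    if basis == "ri":
        return ri
    if basis == "rc":
        return ci * ri
    raise WeightingError(f"unknown weighting basis {basis!r}")


def reweight(
    matrix: CharacterMatrix, tree_set, basis: str = "rc", fit: str = "max"
) -> np.ndarray:
    """Weight vector from the per-character indices over a tree set.

    ``fit`` picks how a character's index is combined across equally good
    trees: its best (max), worst (min) or mean value.
    """
    trees = list(tree_set)
    if not trees:
        raise WeightingError("empty tree set")
    if fit not in ("max", "min", "mean"):
        raise WeightingError(f"unknown fit mode {fit!r}")
    m, g = char_bounds(matrix)
    per_tree = []
    for t in trees:
        s = per_character_steps(t, matrix)
        per_tree.append(
            [_char_index(int(s[c]), int(m[c]), int(g[c]), basis) for c in range(matrix.n_char)]
        )
    arr = np.asarray(per_tree, dtype=np.float64)
    if fit == "max":
        w = arr.max(axis=0)
    elif fit == "min":
        w = arr.min(axis=0)
    else:
        w = arr.mean(axis=0)
    return w


@dataclass
class SWIteration:
    index: int
    weights: np.ndarray
    result: SearchResult


@dataclass
class SWTrace:
    """Iteration history of a successive-weighting run."""

    iterations: list = field(default_factory=list)
    converged: bool = False

    @property
    def final(self) -> SWIteration:
        return self.iterations[-1]

    @property
    def final_weights(self) -> np.ndarray:
        return self.final.weights

    @property
    def final_result(self) -> SearchResult:
        return self.final.result

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "iteration": it.index,
                    "sum_weights": float(np.sum(it.weights)),
                    "best_length": it.result.best_length,
                    "n_trees": it.result.n_trees,
                }
                for it in self.iterations
            ]
        )


def _topology_key(result: SearchResult) -> frozenset:
    return frozenset(t.canonical_newick for t in result.binary_trees)


def successive_search(
    matrix: CharacterMatrix,
    search_config: SearchConfig | None = None,
    basis: str = "rc",
    fit: str = "max",
    max_iter: int = 20,
) -> SWTrace:
    """Iterate reweight-and-research until the best tree set is stable.

    Iteration 0 is the equal-weight search.  Non-convergence at
    ``max_iter`` returns the trace with ``converged=False`` and a warning
    rather than raising.
    """
    if max_iter < 1:
        raise WeightingError("max_iter must be >= 1")
    if search_config is None:
        search_config = SearchConfig()
    weights = as_weights(None, matrix.n_char)
    result = heuristic_search(matrix, weights, search_config)
    trace = SWTrace()
    trace.iterations.append(SWIteration(0, weights, result))
    for it in range(1, max_iter + 1):
        weights = reweight(matrix, result.binary_trees, basis, fit)
        new_result = heuristic_search(matrix, weights, search_config)
        trace.iterations.append(SWIteration(it, weights, new_result))
        if _topology_key(new_result) == _topology_key(result):
            trace.converged = True
            break
        result = new_result
    if not trace.converged:
        warnings.warn(
            f"successive weighting did not converge in {max_iter} iterations",
            stacklevel=2,
        )
    return trace


def final_profiles(trace: SWTrace, matrix: CharacterMatrix):
    """Per-tree fit profiles under the final weights (the paper-style
    per-tree weighted length / CI / RI report)."""
    w = trace.final_weights
    return [fit_indices(t, matrix, w) for t in trace.final_result.binary_trees]
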