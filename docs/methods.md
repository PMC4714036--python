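# Methods

This note documents the model, algorithms, parameter defaults, and numerical
choices in `morphoclad`, plus the deliberate limitations.

## Data model

A character matrix is `n_taxa × n_char` discrete states in `{0..9}` with a
missing code (`?` and `-` in NEXUS both map to missing). Characters are
**unordered** (Fitch): any state-to-state change costs 1. Polymorphic cells
are rejected at parse time. Matrices are immutable after construction
(read-only numpy array); taxa must be unique and `n_taxa ≥ 4`.

Missing data never force changes: a missing leaf carries the full mask of the
character's observed states, and an entirely missing character is scored with
a single dummy state (length 0).

## Tree representation

Trees are unrooted, leaf-labelled; binary for search, possibly multifurcating
after zero-length-branch collapse or consensus. Topology identity is by
canonical Newick (splits canonicalized to the side not containing taxon 0).
Rooting for mapping and monophyly uses declared outgroups: the tree is rooted
on the edge separating the outgroup block when it forms a split, otherwise on
the pendant edge of the first outgroup.

## Parsimony scoring

Character length is computed by the Fitch pass over bitmasks (uint8, up to
8 observed states per character), JIT-compiled with numba. Weighted length is
`Σ w_i s_i` with `w_i ∈ [0, 1]`. Per-character bounds: `m_i` = (number of
observed states − 1); `g_i` = star-tree length, i.e. (number of scored leaves)
minus (count of the most frequent observed state among scored leaves).
Ensemble indices CI, HI, RI, RC follow the standard definitions over summed
`s`, `m`, `g`, including uninformative characters (matching common practice
in the classic software this emulates). Degenerate cases: `s = 0` or
`g = m` give per-character fit 1.

## Search

- **Branch and bound** (`branch_and_bound`, ≤ 12 taxa): taxon insertion
  ordered by decreasing cost contribution, pruning on partial length;
  returns the complete optimal set. Used as the exact oracle.
- **Heuristic** (`heuristic_search`): random-addition stepwise starts
  (ties at each insertion broken by canonical-topology order, so runs are
  reproducible given a seed), then TBR branch swapping to a local optimum.
  With `multrees` (default on), an equal-length TBR plateau walk collects
  the most-parsimonious set up to `maxtrees` (default 100; `auto_extend`
  doubles the buffer when full). Trees are deduplicated after collapsing
  zero-minimum-length branches, so the reported MPT count refers to
  collapsed topologies; the binary pre-collapse trees are retained for
  rescoring. Defaults: `n_replicates=20`, `hold=1`, `swap="tbr"`.
  TBR has genuine local optima even on small matrices; more random-addition
  starts are the remedy (the test suite uses 20 starts for 9-taxon oracle
  comparisons after verifying one such optimum by exhaustive neighbor
  enumeration).

## Successive weighting

`successive_search` iterates: search under current weights → set each
`w_i` to its fit index over the current tree set (basis `rc`, taken as the
**max** over trees, both configurable; `ci`/`ri`, `min`/`mean` also
implemented) → repeat until the canonical binary-topology set is unchanged
(`max_iter=20`). On homoplasy-free data the first iteration is already a
fixed point (all weights 1). The trace records per-iteration weights, tree
counts and lengths.

## Bootstrap

Nonparametric bootstrap resamples characters with replacement (`n_boot`
replicates); each replicate runs a reduced-effort search (pipeline defaults:
10 starts, hold 1, maxtrees 16) and each split found receives `1/|MPT set|`
of that replicate's vote. Support is reported as a percentage per split.
Resamples that are entirely uninformative leave all topologies tied; the
plateau walk then spreads the vote evenly, which the test suite checks
against the analytic expectation for a single informative quartet character.

## Ancestral mapping

Per character, a Sankoff-style up/down dynamic program yields, for every
branch, the set of state pairs realized by at least one MPR. A change is
**unambiguous** when every MPR places the same `from→to` change on that
branch. Classification of unambiguous changes within a character:
*apomorphy* (derived state arises once and no descendant change returns to a
state ancestral at its origin; a further change to a new state does not
demote it), *parallelism* (same derived state arises on ≥ 2 branches),
*reversal* (return to an ancestral state), *parallel reversal* (both).
Changes on the outgroup side of the root are reported but not classified.
Note that a lone change on a root-adjacent branch can slide across the root
in an equally good reconstruction and is therefore never unambiguous; this
is a property of unrooted parsimony, not an implementation artifact.

## Group diagnosis

For a disjoint cover of the ingroup by named groups, `diagnose_groups`
reports per group the (character, state) pairs that are *definitive* (every
scored member has the state, no scored non-member does), *exclusive* (some
member, no non-member), and *common* (every scored member, and also some
non-member). Missing cells are ignored on both sides. `test_monophyly`
checks whether a member set is a clade of a rooted tree and, if not, returns
the intruders of the smallest clade containing the group.

## Synthetic-data generator

`simulate.sample_topology` draws uniform binary topologies by random edge
insertion. `evolve_matrix` evolves each character from state 0 down the
tree, switching state on each edge with probability `p`, and logs every
change as (character, clade, from, to) — the log replays exactly to the
matrix and is the ground truth for recovery tests. Options: per-character
state counts, missing blocks (row × column rectangles), and
`ensure_variable=True`, which redraws a character (≤ 200 attempts) until at
least two states appear among the leaves — matrices in this tradition are
compiled from variable characters only, so validation at very low `p` uses
this to avoid uninformative columns. `make_paperlike` produces a 25-taxon ×
36-character matrix with two outgroups forming a cherry, a fixed set of
three-state characters, and correlated missing blocks (6 taxa unscored for
9 male-genitalic characters, 4 taxa for 6 female characters), all variable.

## Numerical choices

- All kernels use exact integer arithmetic on bitmasks; float comparisons of
  lengths use a 1e-9 tolerance; fit-index identities hold to 1e-12.
- Seeds are plain integers; derived sub-seeds are drawn as
  `rng.integers(0, 2**31 − 1)` so they remain valid across RNG backends.
- Weighted search multiplies integer step counts by float weights; weighted
  lengths are reported to 2 decimals in text output but kept at full
  precision internally.

## Open design decisions

- Stepwise-addition tie-breaking uses canonical-topology order at the hold
  cut; other deterministic orders would be equally valid.
- ACCTRAN/DELTRAN-style selections are implemented as greedy top-down picks
  over the exact per-edge MPR pair sets; classification uses the full MPR
  set (unambiguous changes only), so the choice does not affect reported
  counts.
- The MPT count is defined on collapsed topologies; counting binary trees
  instead would inflate it on matrices with unsupported branches.

## Limitations

- Unordered characters only (no ordered/step-matrix costs), no polymorphic
  cells, ≤ 10 states.
- Branch and bound is practical only to ~12 taxa; the heuristic has no
  optimality guarantee (use more random-addition starts for hard matrices).
- Bootstrap support uses equal vote-splitting across the MPT set; other
  conventions (strict-consensus per replicate) would give slightly different
  numbers.
- The generator's change-per-edge model is not a proper time-reversible
  Markov process; it is designed for controllable homoplasy and exact
  ground-truth logging, not for statistical realism.
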