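# morphoclad

Maximum-parsimony phylogenetics for morphological character matrices, in the
style of classical insect-systematics studies: equal-weight and
successively-weighted parsimony searches, bootstrap clade support, consensus
trees, ensemble fit indices, unambiguous ancestral-state mapping with
apomorphy/parallelism/reversal classification, and character-based diagnosis
of species groups.

## Scientific problem

A taxonomic revision typically scores a few dozen discrete morphological
characters (sclerite shapes, setal counts, genitalic structures) across a few
dozen species plus outgroups, then asks:

1. **Which tree(s) best explain the matrix?** Under the parsimony criterion,
   the preferred trees are those minimizing total length
   `L(T) = Σ_i w_i · s_i(T)`, where `s_i(T)` is the minimum number of state
   changes character *i* requires on topology *T* (Fitch length for unordered
   characters) and `w_i` are character weights.
2. **How internally consistent is the matrix?** Ensemble fit indices over
   characters: consistency index `CI = Σm_i / Σs_i`, homoplasy index
   `HI = 1 − CI`, retention index `RI = (Σg_i − Σs_i) / (Σg_i − Σm_i)`, and
   rescaled consistency `RC = CI·RI`, where `m_i` is the minimum conceivable
   and `g_i` the maximum (star-tree) number of changes.
3. **Can conflicting signal be down-weighted?** Successive approximations
   weighting: rescore, set `w_i` to each character's fit (here the rescaled
   consistency, taken as the **max** over the current tree set), and repeat
   until the tree set is stable.
4. **Which changes are unambiguous, and what kind are they?** Changes shared
   by *every* most-parsimonious reconstruction (MPR) of a character are
   mapped onto branches and classified as apomorphies (arise once, never
   revert), parallelisms, reversals, or parallel reversals.
5. **What diagnoses a species group?** For a partition of the ingroup,
   (character, state) pairs that are *definitive* (all members, no
   non-members), *exclusive* (some members, no non-members), or *common*
   (all members, also elsewhere).

`morphoclad` implements this whole workflow with exact small-instance solvers
(branch and bound, ≤ 12 taxa), a TBR (tree bisection–reconnection) heuristic
with random-addition starts for larger matrices, nonparametric bootstrap by
character resampling, and a seeded synthetic-data generator that produces
study-shaped matrices (25 taxa × 36 characters, correlated missing-data
blocks, no invariant characters) with a logged ground truth for validation.

## Worked example

Simulate a study-shaped matrix and analyze it end to end:

```sh
morphoclad simulate --seed 7 --out demo/sim
cat > demo/config.yaml <<'YAML'
replicates: 50
hold: 1
bootstrap_replicates: 100
outgroups: [out1, out2]
seed: 7
YAML
morphoclad analyze --matrix demo/sim/matrix.nex \
                   --config demo/config.yaml --out demo/out
```

Output (actual run):

```text
morphoclad 0.1.0 analysis (seed 7)

EW search: tree length = 113; 1167 most-parsimonious tree(s); CI = 0.336; HI = 0.664; RI = 0.531; RC = 0.179
SW search: converged = True in 2 iteration(s); 1 tree(s)
  SW profile 1 (9 tree(s)): weighted length = 20.69; CI = 0.566; HI = 0.434; RI = 0.733; RC = 0.415
Mapping: 93 unambiguous changes (apomorphies 5, parallelisms 64, reversals 8, parallel-reversals 16)
outputs written to demo/out/
```

`demo/out/` then contains the equal-weight trees and strict consensus
(`ew_trees.nwk`, `ew_consensus.nwk`, `ew_consensus_support.nwk` with
bootstrap labels), fit-index tables (`ew_fit.tsv`), the successive-weighting
trace and trees (`sw_trace.tsv`, `sw_trees.nwk`), bootstrap split supports
(`bootstrap_ew.tsv`, `bootstrap_sw.tsv`), the unambiguous-change table
(`changes.tsv`), and machine-readable `report.json` plus human-readable
`summary.txt`.

The same steps are available as a library:

```python
from morphoclad.search import SearchConfig, heuristic_search
from morphoclad.matrix import read_matrix
from morphoclad.parsimony import fit_indices

m = read_matrix("demo/sim/matrix.nex", format="nexus")
res = heuristic_search(m, config=SearchConfig(n_replicates=50, seed=7))
print(res.best_length, res.n_trees, fit_indices(res.binary_trees, m).CI)
```

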