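# Methods

## Classification model

`rfscreen` trains a binary random forest (active vs inactive) by bagging:
each of `n_trees` decision trees is grown on an independent
*n*-with-replacement bootstrap resample of the training table, node splits
are chosen to maximize GINI impurity gain over a random subset of
`max_features` candidate descriptors, and the ensemble predicts by majority
vote. Out-of-bag row indices are stored per tree in the training summary so
callers can estimate generalization error without a holdout set.

Candidate thresholds at a node are the midpoints between consecutive
distinct sorted values of each candidate feature; for 0/1 fingerprint
columns this degenerates to the single threshold 0.5. The comparison rule is
"go left iff value ≤ threshold". Ties in gain break to the lowest feature
index, then to the lowest threshold, making split selection fully
deterministic.

## Non-recursive hybrid construction

Trees are built iteratively from an explicit frontier (a deque of unexpanded
nodes) instead of recursion. While the number of created nodes is below a
crossover threshold the frontier is popped last-in-first-out (depth-first);
at and beyond it, first-in-first-out (breadth-first). With
`bfs_threshold="auto"` the crossover resolves from the regression

    threshold(n, f) = 3705 + 0.0577·n + 21.84·f,

with `n` the bootstrap sample count and `f = max_features`. The coefficients
are taken as given; they were originally fitted to balance data-parallel
(per-node) against task-parallel (per-level) work on batch-parallel
hardware. At desk scale the threshold has no efficiency consequence, but the
construction-order contract it governs is load-bearing and tested:
predictions must be bit-identical for `bfs_threshold ∈ {0, auto, 10⁹}`.

That invariance holds because all randomness is positional. Stream keys are
derived by SHA-256 from structured tuples — `(seed, "bootstrap", t)` for the
per-tree resample and `(tree_seed, "features", heap_index)` for per-node
feature subsets, where `heap_index` encodes the root-to-node left/right path
(root 1, children 2k and 2k+1) — and feed numpy PCG64 generators. The same
node therefore sees the same candidate features regardless of when it is
expanded, and models are pure functions of `(table, params)` on any
platform.

Feature subsets are drawn per node rather than once per tree. The two
readings are both defensible; per-node sampling is the standard random-forest
formulation, matches the crossover regression's definition of `f` as the
features considered *at each node split*, and is what makes order invariance
testable.

## Termination and leaf labelling

A frontier node is finalized as a leaf when any of the following holds: its
GINI impurity is ≤ `gini_leaf_threshold`; it holds fewer than
`2·min_samples_leaf` rows; it sits at `max_depth`; or no candidate split
achieves gain > `min_gain`. The impurity rule is read as "sufficiently pure
⇒ leaf" (the threshold bounds impurity from above). Leaf labels are the
majority class of the node's bootstrap rows with ties going to *active* —
the same tie rule as forest voting — because in a screening campaign a
false negative (a discarded active) is costlier than a false positive.

Defaults: `n_trees=50`, `max_features=14` (⌈√179⌉), `gini_leaf_threshold=0`
and `min_gain=10⁻⁷` (fully grown trees, as in standard serial forests),
`min_samples_leaf=1`, `max_depth` unlimited.

## Descriptor scheme

Each molecule maps to 179 descriptors in three blocks, computed on the
implicit-hydrogen heavy-atom graph:

* **Drug-likeness (8):** molecular weight, Crippen logP, H-bond donor and
  acceptor counts, rotatable bonds, topological polar surface area, ring
  count, heavy-atom count.
* **BCUT-style (24):** the 4 lowest and 4 highest eigenvalues of the Burden
  connectivity matrix under three diagonal weightings — atomic mass, Pauling
  electronegativity, covalent radius. Off-diagonal entries are 0.1 × a
  bond-order weight (single 1, aromatic 1.5, double 2, triple 3), +0.01 when
  an endpoint is terminal, and 0.001 for non-bonded pairs. Graphs with fewer
  than four atoms pad by repeating the extreme eigenvalue.
* **Pharmacophore pairs (147):** 21 unordered pairs of six feature classes
  (H-bond donor, acceptor, aromatic, hydrophobe, positively ionizable,
  negatively ionizable; SMARTS definitions in
  `descriptors._PHARMACOPHORE_SMARTS`) × 7 topological-distance bins
  (bond-path distance 1–6, then ≥ 7). A bit is set iff any atom pair of
  those classes occurs at that distance; same-class pairs require two
  distinct atoms.

This is a documented structural stand-in with the canonical 8 + 24 + 147
block layout: the historical feature-extraction tools that defined the
original panel are proprietary, and no claim of bit-compatibility with them
is made. Downstream code depends only on the block contract (179 finite
values, trailing 147 in {0,1}), which is what the tests assert.

Activity tags parse case-insensitively: active/1/true and inactive/0/false;
anything else (e.g. "Inconclusive") drops the record with a warning rather
than silently entering training.

## Evaluation panel

Recall, precision, accuracy and F-score come from the confusion matrix with
active as the positive class. The ROC area is computed from vote-fraction
scores by the Mann–Whitney rank-sum identity (ties counted ½) — a hard-label
ensemble yields a ranking only through its vote fractions, and this is the
standard resolution. Ratios with zero denominators are reported as NaN (null
in JSON) with a warning, never as 0, so degenerate predictions remain
visible. Train/test splitting is deliberately left to the caller.

## Synthetic bioassay generator

`generate_assay` emulates an imbalanced binary bioassay feature table:
exactly ⌈n·active_fraction⌉ actives (default fraction 0.125, echoing large
public antimycobacterial screens), 32 continuous Gaussian columns
(`noise_sd`, default 1) and 147 Bernoulli bits with base on-probability 0.1
(sparse fingerprints are the realistic regime). `n_informative` columns
(default 20) carry the class signal; they are chosen from the seed,
stratified across the two blocks in proportion to block size so that a given
`effect_size` injects a comparable amount of signal for every seed. Actives
get informative continuous columns shifted by `effect_size·noise_sd` and
informative bit on-probabilities raised by `min(0.1·effect_size, 0.4)`.

What the generator does *not* emulate: real structure–activity
relationships, descriptor correlations, activity cliffs, or assay noise and
label errors. Passing signal-recovery tests therefore demonstrates that the
learner finds linear-ish block-structured signal at realistic imbalance —
not that any particular chemistry is predictable.

`generate_molecules` writes small valid structures (ten scaffold templates ×
ten decorations, enumerated and canonicalized) as paired SDF/SMILES files
with a synthetic ACTIVITY tag, for exercising the parsing pipeline offline.

## Numerical and degenerate-input choices

* Split gains are computed in double precision by cumulative-sum scans; the
  exhaustive-enumeration oracle in the tests agrees to 10⁻¹².
* A training table with a single class is an error, not a trivial model.
* Vote ties, leaf-label ties: active (documented above).
* Molecules whose featurization fails during screening are recorded with
  status `failed` and screening continues; in `featurize` (training path)
  the failure is fatal with row context, since silently dropping training
  rows would bias the model.
* Model JSON carries a `format_version`; loading any other version fails.

## Problem sizes in the test suite

The behavioural suites run at desk scale chosen for statistical adequacy:
split-oracle comparison on 100 random instances (≤ 200 rows × ≤ 10
features), order invariance on 20 assays of n=500, signal recovery at
n=1000 with 50 trees, chance-ROC at effect 0 averaged over 20 seeds,
reference-forest agreement on 5 assays of n=800, and monotonicity of
held-out accuracy in effect size over {0, 0.5, 1, 2} at n=600 averaged over
5 seeds. The full suite completes in well under a minute on one CPU.

## Known limitations

* Binary classification only; no regression trees, multiclass targets, or
  pruning.
* The descriptor panel is a structural equivalent, not a reproduction of
  any proprietary tool's values; models are not transferable to tables
  featurized by other software.
* Batched screening is backend-agnostic and single-process; no GPU kernels
  or asynchronous I/O overlap.
* The crossover regression's coefficients are hardware-era constants taken
  as given; on this backend the threshold only fixes construction order.
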