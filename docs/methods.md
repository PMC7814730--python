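# Methods

`dilimine` implements a structure-based analysis of drug-induced liver
injury (DILI): binary classification of compounds from their chemical
structure, biological interpretation of predicted protein-target features,
and mining plus statistical evaluation of structural alerts. This note
documents the models, the numerical conventions, and the synthetic study
conditions the test suite runs under.

## Compound curation

Input structures are standardized before anything else sees them:
carbon-free fragments (counterions, water, inorganic solvents) are removed,
duplicate organic fragments (salt stoichiometry) collapsed, the remaining
fragment neutralized where possible, and the tautomer canonicalized with
the RDKit rule set; output is canonical SMILES and the whole map is
idempotent. Distinct organic fragments are deliberately *kept* at this
stage so that true multi-ingredient mixtures remain visible to the filter
step, which rejects, in order: mixtures (≥ 2 distinct organic components),
inorganics (no carbon), metal-organics (any atom outside
H,B,C,N,O,F,Si,P,S,Cl,Se,Br,I), and parents above 1000 Da (strict
inequality — "above 1 kDa" read as exclusive). Every rejection carries its
rule; `|input| = |kept| + |rejected|` holds per stage.

Cross-source duplicates are resolved by canonical-SMILES identity in favor
of the severity-annotated source (the text-mined inactive record is
dropped). Note that organic–organic salts (tosylates, maleates) are flagged
as mixtures rather than stripped; for the synthetic inputs this case does
not arise, and real inputs would need a salt dictionary.

Three labeling schemes binarize the severity classes: `minus_vLess`
(vMost → DILI, vNo → NoDILI, everything else excluded — the high-confidence
scheme), `full` (adds vLess to DILI), and `plus_SIDER` (adds text-mined
inactives to NoDILI). The scheme compound sets are nested.

## Features and similarity

ECFP4 means Morgan radius 2 (diameter 4), folded to 2048 bits, binary
presence (hashed-count variants are not used). Fingerprints are never
scaled. Continuous descriptor matrices are standardized to zero mean and
unit variance with the population (1/n) variance convention; constant
columns map to zero. The scaler has a strict fit/apply split and every
fitting path in cross-validation only ever sees training rows — an
instrumented test asserts this.

Tanimoto similarity is |A∩B|/|A∪B| on the bit sets, with the convention
that two all-zero vectors have similarity 1 (identical objects). Clustering
is single-linkage (nearest point) on distance 1 − similarity, cut at 0.5;
merges at exactly 0.5 are applied, so any pair with similarity ≥ 0.5 shares
a cluster. Under that cut single linkage is equivalent to connected
components of the similarity ≥ 0.5 graph, which the tests exploit as a
union-find oracle. Cluster labels are renumbered by smallest member index
so fold construction is stable across runs.

## Cross-validation and models

The evaluation scheme is a 5-fold leave-one-cluster-out (LOCO) grid search
nested in a 10-fold stratified training scheme. The outer split is
stratified on the label only (clusters may span outer folds — a faithful
reproduction of the source scheme; `strict_loco_outer=True` groups them).
Within each outer training fold, whole clusters are packed greedily into 5
balanced, cluster-disjoint groups (group-disjointness is the contract;
balance is our determinism choice), guaranteeing that no inner
train/validation pair exceeds Tanimoto 0.5.

Hyperparameter grids are stored verbatim: linear-kernel SVM with balanced
class weights and C ∈ {0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1}; random forest
with balanced-subsample class weights, max depth ∈ {10, 15, ∞}, min
samples per leaf ∈ {1, 2, 3}, and 100–1000 trees. The winner maximizes
mean inner balanced accuracy; ties go to the first (simplest)
configuration in declaration order — smallest C, shallowest tree, fewest
estimators. Degenerate single-class inner folds are skipped with a
warning; metrics average over the rest.

Balanced accuracy is (TP/(TP+FN) + TN/(TN+FP))/2 and raises an explicit
error when a class is absent rather than propagating NaN. Across-fold
dispersion is reported as the sample standard deviation (ddof = 1).
Chance-level baselines come from y-scrambling: labels permuted before the
*entire* procedure (fold construction included), three runs with distinct
child seeds, median reported. The similarity–response analysis
leaves each compound out, refits, and bins the mean Tanimoto similarity to
its 5 nearest training neighbors into left-closed bins of width 0.1;
empty bins carry a null rate and one-compound bins are flagged.

Feature importances are impurity-decrease fractions (summing to 1) for the
forest and signed hyperplane coefficients for the linear SVM, aggregated
across the 10 outer folds by the median; ranking uses |median| for signed
coefficients.

## Target interpretation

DILI-enriched features come from a one-sided rank-sum test for higher
values in the DILI class with Benjamini-Hochberg control at FDR < 0.05
(our own step-up implementation, oracle-tested against statsmodels).
Three p-value paths are used: full enumeration of group assignments over
midranks for small samples (total ≤ 20); an exact hypergeometric tail for
two-valued columns at any sample size (the rank-sum statistic for binary
data is monotone in the count of ones in the DILI group, so its
permutation distribution is hypergeometric — the normal approximation is
measurably anti-conservative in the far tail for such data); and the
tie-corrected, continuity-corrected normal approximation otherwise.
Constant features report p = 1 rather than erroring. Binary activity calls
and continuous binding probabilities are both accepted; the test is
rank-based either way.

Over-representation analysis is a hypergeometric upper tail on a fixed
background (the full feature list), with genesets holding fewer than 10
background members excluded and BH across the retained sets. The threshold
scan selects features that are both significantly enriched and above an
importance cutoff — either a quantile of |median importance| or the top-k
by rank (the headline analysis uses k = 19) — and reruns the ORA per
cutoff.

## Structural-alert mining

Two miners emit candidate alerts as aromaticity-aware SMARTS (aromatic
atoms lowercase). Support is always the number of matching molecules, not
embeddings, counted with the same matcher the evaluation uses, so mined
and evaluated supports cannot drift apart.

The **graph miner** grows fragments depth-first from single-atom seeds.
A candidate is pruned as soon as its focus-class (DILI-positive)
occurrence falls below ceil(mfs·|positives|) — sound because molecule
support is anti-monotone under extension. Rings are mined atomically: when
a ring bond enters a fragment, the whole ring (closed over fused systems)
enters with it, so partial rings are never emitted; this also means every
fragment inherits its aromatic perception directly from its parent
molecules, eliminating the subgraph→SMARTS aromaticity mismatches that
plague graph miners whose fragments are perceived independently. Emitted
alerts have 2–15 bonds, at least one non-carbon atom, and complement
occurrence ≤ floor(mcs·|negatives|); with the default mcs = 0.01% the
floor is 0 on any realistic set, which is why mined alerts have precision
1 on the mining set. Fragment identity during the search is the canonical
SMILES of the subgraph; duplicates are pruned globally.

The **fragment miner** cuts acyclic single bonds: rigid blocks (ring
systems, multiple bonds) are contracted into nodes of a tree, and every
connected subtree yields a fragment, which is exactly the set of pieces
obtainable by recursively breaking any combination of acyclic single
bonds. Fragments are size-filtered to 2–15 heavy atoms, validated against
the whole dataset, and retained when hits ≥ 5, likelihood ratio ≥ 1 and
precision ≥ 0 (defaults). The likelihood ratio is precision over the
positive prior, LR = (TP/(TP+FP)) / (P/(P+N)), with FP substituted by 0.5
when zero so clean fragments get a finite LR that still grows with TP.
Rule extraction is greedy in (LR, hits) order, dropping any fragment whose
matched positives are a subset of an already accepted rule's. Molecules
with more than 60 breakable bonds trigger a sampling fallback with a
warning. Ring cleavage is deliberately out of scope.

## Alert evaluation

Alerts are matched by aromaticity-aware substructure containment.
Per alert: TP/FP on the evaluation set, precision TP/(TP+FP) (null when
nothing matches), coverage as percent of DILI positives matched, and a
one-sided (greater) Fisher exact p on the matched/unmatched × DILI/NoDILI
table, significant at p ≤ 0.05 inclusive and uncorrected (a BH option
exists, off by default for fidelity to the source convention). By default
alerts are evaluated on the mining set itself, which optimistically biases
the precision of mined alerts — a held-out evaluation mode exists and
should be preferred when the data allow. A catalog screen counts matches
in an approved-drug table and reports exemplars.

## Synthetic study conditions

The generator is first-class, seeded code. Molecules are assembled by
joining 1–3 random scaffold fragments with single bonds at H-bearing
atoms; carrier compounds additionally get the toxicophore fragment grafted
by one single bond. Assembled bodies are rejection-sampled to match no
planted pattern, so non-carriers are guaranteed clean, and every emitted
SMILES is passed through the curation standardizer so the generated tables
are already in standard form. Carrier counts are exact
(round(prevalence·n) chosen without replacement) so tests can assert exact
occurrence; a Bernoulli mode exists behind a flag. One integer seed drives
named child RNG streams; there is no hidden global state.

Defaults — the study conditions used throughout the tests and the
acceptance script, chosen once: 200 positives + 200 negatives; two planted
toxicophores, hydrazine `NN` and furan `c1ccco1`, at 10% positive and 0%
negative prevalence; 100 binary target features of which the first 20
carry a +0.4 probability shift over a 0.3 negative-class base rate;
one planted geneset holding exactly the planted features plus 20 random
decoy sets; a 50-compound decoy drug catalog in which roughly a fifth of
entries carry a planted toxicophore. The Wilcoxon power check uses
n = 500 (250 per class) at the same +0.4 shift.

What the generator does *not* emulate: realistic drug-likeness or
molecular-property distributions, stereochemistry, correlated target
features, label noise, and class-imbalanced severity structure. Passing
tests therefore demonstrate correctness and calibration of the machinery
and recoverability of planted signal under clean conditions — not
real-data performance, which in the underlying problem is bounded by label
quality and chemical-space coverage.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at the
200+200 study scale, where a complete linear-SVM nested run takes seconds;
the random-forest path is exercised with reduced grids in unit tests while
the full published grid remains the stored default. The effect-size
monotonicity check uses 10 seeds × 3 effect levels with a one-sided
signed-rank trend test; null-FDR calibration uses 200 replicates; the
miner-equivalence oracle uses 30 random molecules of ≤ 12 heavy atoms with
a 5-bond cap. Tolerances in tests are either exact (enumeration oracles,
closed forms, exact-count planting) or 3-sigma binomial bands where the
quantity is genuinely stochastic.

## Known limitations

* Tautomer canonicalization follows the RDKit rule set, which is related
  to but not identical with the standardizer cited for the original data
  preparation; both are idempotent canonical maps.
* The graph miner's embedding enumeration is exponential in fragment size
  in the worst case; it is intended for alert-scale fragments (≤ 15
  bonds) on drug-sized molecules, not for arbitrary frequent-subgraph
  workloads.
* Conflicting severity labels for the same standardized structure within
  one source raise rather than being resolved heuristically.
* Duplicate compound identity is canonical-SMILES equality; InChI-based
  identity and stereochemistry-aware deduplication are out of scope.
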