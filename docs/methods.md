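# Methods

## Problem and model

Most metabolomics datasets contain many metabolites with no known pathway
annotation.  Supervised models can predict whether a metabolite is involved
in a broad metabolic pathway category (e.g. the 12 topmost KEGG metabolism
categories), but the usual design — one binary classifier per category —
multiplies training cost and dilutes the positive examples available per
model.  `pathpairs` implements the alternative: a **single generic binary
classifier** whose input is a *metabolite-pathway feature pair* — the
concatenation of a metabolite's feature vector with a pathway category's
feature vector — and whose label says whether that metabolite belongs to
that category.  One model then serves every category, including categories
never seen as a fixed output head.

Metabolite features are counts of *atom colors*: string-encoded
substructures (an atom plus its bonded neighborhood up to some depth, the
*bond-inclusion level*; level 0 is the bare element).  Computing atom
colors from molecular structures is upstream of this package; matrices of
counts are consumed, not produced.

## Feature engineering

1. **Aggregation.**  A pathway category's raw feature vector is the sum of
   its member metabolites' count vectors: entry (p, f) is the number of
   occurrences of atom color f across all metabolites in category p.
2. **Per-bond-level normalization.**  Raw sums are incomparable across
   categories with different membership sizes, so each value is divided by
   the total count of all atom colors *of the same bond-inclusion level* in
   the same row — a proportion.  A carbon count of 1,000 against a 10,000
   elemental-level total becomes 0.1.  Metabolite rows are normalized with
   the identical rule for consistency.  The operation is idempotent and
   invariant to rescaling any one (row, level) group by a positive
   constant; groups with zero total stay zero.  The term "softmax" is
   sometimes attached to this step in the literature; the arithmetic
   implemented (and the only one consistent with the 1,000/10,000 → 0.1
   example) is the plain sum-proportion, not the exponential softmax.
3. **De-duplication.**  With only a dozen pathway rows, many pathway
   columns carry identical value vectors.  Duplicates are removed keeping
   the first occurrence in column order, recorded in a reversible alias
   map (`DedupMap`) that reconstructs the original matrix bit-exactly.
   Comparison is exact by default (`tolerance=0`): normalized values are
   exact ratios, and identical count columns normalize to identical
   doubles.  A positive absolute tolerance is exposed for noisy inputs.
   De-duplication runs *after* normalization; columns with equal raw
   counts remain equal after normalization, so the order only matters for
   columns that become equal through normalization, and comparing the
   values the classifier actually sees is the safer convention.
4. **Min-max scaling and auto-encoding (optional).**  For the encoded
   variant, the metabolite block and the *non*-de-duplicated pathway block
   (same width, same atom-color vocabulary) are stacked vertically,
   min-max scaled feature-wise, and used to train a single auto-encoder.
   Constant features scale to 0, preserving sparsity.  The latent width is
   `floor(width x ratio)` with ratio 0.1 by default, so 14,655 columns
   compress to 1,465.  Latent outputs are min-max scaled again (parameters
   fit on the stacked encoded rows) to give final encoded features in
   [0, 1].

The auto-encoder is a symmetric fully connected network — input → hidden →
latent → hidden → output, ReLU activations, mean-squared-error
reconstruction loss, mini-batch Adam, optional early stopping on a held-out
reconstruction loss — built on scikit-learn's multilayer perceptron
regressor fit to reproduce its own input; encoding is a manual forward pass
through the first two weight matrices.  The hidden width defaults to twice
the latent width.  Architecture, epochs, batch size, learning rate and
stopping are configurable (`EncoderTrainConfig`); these defaults are this
package's own choices.

## Pair construction

The pair dataset is the Cartesian product: every metabolite against every
pathway category, in fixed metabolite-major order (catalog order within a
metabolite) so that seeded splits are reproducible.  Entry count is
`n_metabolites x n_pathways`; vector width is the sum of the two block
widths; label 1 iff the metabolite is in the category's membership set;
metabolites in no category contribute all-negative pairs.  The dataset is
*virtual*: a 68,196 x 20,090 dense matrix is never stored; train/test
splits and oversampled training sets are index views over the two blocks,
materialized only when a model needs a dense array.

## Evaluation protocol

Each CV iteration:

- **Stratified split** of pair entries, default test fraction 0.15
  (unstated upstream; configurable), stratified jointly on
  (pathway, label) by default so every category appears in every test set
  and per-pathway MCC is always computable.  Label-only stratification and
  an opt-in metabolite-grouped mode (keeping all of a metabolite's pairs
  on one side, as a leakage control) are available.  Splits are made at
  the pair level: the same metabolite may appear in train and test under
  different pathways.
- **Positive oversampling** of the training set only: each positive entry
  is duplicated to appear `k = floor(n_neg / n_pos)` times (k >= 1), the
  largest integer multiple keeping the positive proportion at or below one
  half.  Test sets are never oversampled — duplicate test entries inflate
  scores.
- **Fit and score.**  Backends: gradient-boosted trees (XGBoost,
  `hist` tree method) and a multilayer perceptron (scikit-learn), both
  seeded; prediction threshold 0.5.  Metrics: accuracy, precision, recall,
  F1 and MCC, computed from the confusion matrix with every
  zero-denominator case defined as 0.  MCC is the headline metric under
  ~10% positive imbalance.  Per-pathway records are the same metrics on
  the test pairs of each category; their confusion counts partition the
  overall counts.  Per-iteration seeds are `base_seed + iteration` for
  auditability.  Overall summaries are reported both as the mean/sd of the
  per-iteration all-pairs MCC and (via `summary()`) per pathway.

**Hyperparameter tuning** is seeded random search: each trial samples a
configuration from an editable search space (tree depth / learning rate /
estimators / subsampling for the tree backend; layer sizes / learning rate
/ regularization / batch size / epochs for the perceptron), runs up to a
capped number of CV iterations, and is scored by its **median** test MCC.
Median pruning stops a trial early when, after a warm-up, its running
median falls below the median of earlier completed trials' running medians
at the same iteration count.

**Feature importance** is defined for the tree backend only (the
perceptron has no comparable per-feature score; requesting it raises an
explicit error).  Per iteration, raw gain-based scores are normalized to
proportions over all features, features scoring 0 in every iteration are
excluded, the proportions are averaged across iterations and ranked
descending with ties broken by column order.  An exponential-softmax
normalization is available behind a flag; the proportional form is the
default for consistency with the normalization step above.  Each feature
carries its origin block; the rank of the same atom color in the other
block is attached when that counterpart exists and was included.  A
feature's associated pathways are the categories whose *raw* summed count
for that atom color is positive.

## Synthetic data

`generate(SynthConfig)` draws a seeded count matrix and catalog with the
structure the method assumes: Poisson counts (negative binomial behind
config) at `base_rate`, pathway memberships as independent Bernoulli draws
at `membership_probability = 0.106` (matching the ~10.6% positive-pair
imbalance of the KEGG-derived benchmark), bond levels assigned round-robin,
and a disjoint signature feature set per pathway whose rates are multiplied
by `1 + signal_strength` for members.  Defaults — 300 metabolites, 6
pathways, 200 features, signature size 10, signal strength 5 — give a
fixture both backends can learn well above chance within seconds to
minutes on one CPU; those sizes are the package's standard desk-scale study
conditions and all shipped tests use them or smaller.  `signal_strength=0`
is the null construction: signature and background columns identically
distributed, so test MCC sits at chance.

`planted_separable` is the deterministic extreme: one designated feature
per pathway is positive exactly for that pathway's members and *all other
columns are zero*, so labels are a function of the pair features, a tree
can reach in-sample MCC 1, and importance must concentrate on designated
columns.

What the generator does **not** emulate: real substructure co-occurrence
(valence, chemistry), KEGG's exact sparsity and duplicate-column profile,
correlated pathway memberships, or the 5,683 x 14,655 benchmark scale.
Passing tests therefore demonstrate the correctness and calibration of the
pipeline machinery, not field performance on KEGG; the published benchmark
numbers additionally require the released benchmark data and around a
thousand CV iterations.

## Numerical conventions and edge cases

- Matrices reject negative, non-finite values and duplicate ids at
  construction.
- Empty pathway membership is an error, not a zero row (a zero pathway
  vector is meaningless after proportion normalization).
- Constant columns min-max scale to 0.
- MCC, precision, recall, F1 are 0 whenever their denominator is 0.
- Oversampling requires both classes; single-class training sets raise.
- Stratified splitting requires every stratum to hold at least 2 entries.
- Bond level is explicit per-column metadata supplied with the input
  matrix; no grammar is assumed for atom-color identifier strings.

## Storage

Results persist to a single SQLite database file (tables `runs`,
`iterations`, `metrics`, `trials`, `importance`) with CSV export; the run
configuration is embedded JSON so a stored run can be reproduced from the
database alone.  Matrices travel as HDF5 (values + ids + bond levels) or
CSV with a bond-level sidecar TSV; catalogs as JSON or two-column TSV;
de-dup maps and encoder weights as JSON/NPZ.

## Known limitations

- The auto-encoder runs full-batch epochs through scikit-learn; at the
  published benchmark width (14,655) training it is a substantial compute
  job and is not exercised by the shipped tests, which verify the width
  contract, determinism and reconstruction quality at smaller widths.
- Tree training materializes the oversampled training block densely; at
  benchmark scale this requires memory proportional to
  `n_pairs x pair_width`.
- The tuner's search spaces are pragmatic defaults, not a reproduction of
  any published search space.
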