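# Methods

## Problem setting

Given m drugs, a symmetric binary interaction matrix Y (Y_ij = 1 when an
interaction between drugs i and j is recorded) and one or more m×m
drug-similarity matrices ("views") with entries in [0, 1], the pipeline
predicts, for every unordered drug pair, the probability that the pair
interacts. A zero in Y means *no interaction recorded*, not a verified
non-interaction; zeros are nevertheless treated as negatives during
training and evaluation, the standard approximation in this setting, which
biases measured precision and F downward relative to their true values.

The pipeline has four stages, each usable on its own through the library
API and together through the `ndd` command line tool.

## 1. Gaussian Interaction Profile (GIP) kernel

Drug i's interaction profile Y_i is column i of Y. The GIP similarity is

    GIP(i, j) = exp(−γ_d ‖Y_i − Y_j‖²),
    γ_d = γ̃_d / ( (1/m) Σ_i ‖Y_i‖² ),

with γ̃_d = 1 by default. Dividing by the mean squared profile norm (for
binary Y, the mean interaction count per drug) makes the kernel bandwidth
independent of dataset size. GIP is symmetric with unit diagonal and
entries in (0, 1].

Because GIP is a function of the labels being predicted, the evaluation
computes it per training fold from a *masked* copy of Y in which both
ordered entries of every held-out pair are zeroed (`gip_scope="fold"`, the
default). A faster `gip_scope="global"` computes it once from the full Y;
it is provided for comparison but lets held-out labels shape the features
and should not be used for honest error estimates.

## 2. Entropy-based similarity selection

Each candidate view A (the loaded views plus GIP by default) is scored by
the mean Shannon entropy of its row-normalized distributions
p_ij = a_ij / Σ_k a_ik, using natural logarithms and the 0·log 0 = 0
convention. Near-uniform rows (entropy near log m) carry little
information, so views with entropy above c1·log m are discarded
(c1 = 0.6). Survivors are ranked by ascending entropy and pruned greedily:
the lowest-entropy view is selected, then every remaining view whose
affinity S = 1/(1 + D) with it exceeds c2 = 0.6 is eliminated as
redundant, where D is the entrywise (Frobenius) Euclidean distance; the
loop repeats until the ranked list is empty.

Numerical choices: ranking ties break lexicographically by view name; row
normalization includes the diagonal (an `exclude_diagonal` switch exists
for sensitivity analysis); a zero-sum row contributes entropy 0 with a
warning; the comparison E > c1·log m is base-invariant, so the natural log
is used on both sides. When only one view is supplied (or survives),
selection and fusion pass it through unchanged — the single-view fallback
that a one-similarity dataset requires.

Note that whether GIP survives the filter depends on the density of the
interaction matrix: for small, dense panels its rows are spread widely and
it can legitimately be dropped as high-entropy, which is the observed
behaviour on the default synthetic benchmark.

## 3. Similarity Network Fusion (SNF)

The selected views are fused by iterative KNN cross-diffusion. Each view W
yields a global kernel P (P_ij = W_ij / 2Σ_{k≠i} W_ik off-diagonal,
P_ii = 1/2; row-stochastic) and a local kernel S supported on each row's K
largest off-diagonal entries, row-normalized, with ties broken toward the
lower column index. For T iterations every view's global kernel is updated
simultaneously as

    P⁽ᵛ⁾ ← S⁽ᵛ⁾ · mean_{u≠v} P⁽ᵘ⁾ · S⁽ᵛ⁾ᵀ,

then symmetrized, regularized by adding `alpha_reg` (default 1.0) to the
diagonal, and row-renormalized, so every intermediate stays row-stochastic
to machine precision. The fused matrix is the symmetrized mean of the T-th
iterates. Defaults K = 20 (capped at m−1) and T = 20. Simultaneous
updates make the result invariant to the order of the input views; a fixed
iteration count (no early stopping) keeps runs deterministic. Inputs are
used as validated, already in [0, 1], with no further rescaling.

## 4. Pair classifier

A pair (i, j) is represented by concatenating rows i and j of the fused
matrix (2m features). The representation is ordered while the label is
symmetric, so training uses both orderings of each training pair and
evaluation scores an unordered pair as the mean of its two directional
scores.

The network is Dense(300) → ReLU → Dropout(0.5) → Dense(400) → ReLU →
Dropout(0.5) → Dense(1) → sigmoid, trained with mini-batch SGD (momentum
0.9, batch 200) on binary cross-entropy; weights start from N(0, 0.05²)
and biases from U(−1, 0). It is implemented as a compact numpy
feed-forward network inside the package (`ndd.network`), with inverted
dropout (disabled at prediction time, so prediction is deterministic) and
all randomness drawn from a single seeded generator, which makes
train→predict bit-reproducible.

Two practical notes on this configuration:

- The U(−1, 0) bias initialization is kept as specified, but it puts most
  rectifier units below threshold when inputs are small — and SNF rows are
  row-stochastic, i.e. on a 1/m scale. Features are therefore z-scored on
  the training set by default (`standardize=True`; the scaler is stored in
  the model). A `bias_init="zeros"` switch exists and is what we recommend
  for narrow networks, where the negative-bias initialization can leave
  the whole hidden layer dead.
- The learning rate is not part of the published configuration; the
  default is 0.01 and should be revisited per dataset. Epoch counts are
  dataset-dependent (20 by default; larger, sparser panels benefit from
  50).

Hyperparameter search (`tune_nested_cv`) scores every grid point —
hidden-layer layouts, activation in {relu, tanh, sigmoid}, dropout in
{0.3, 0.5} — by the mean AUPR of a stratified 3-fold run of the full
pipeline and returns the best, ties going to the first point in
enumeration order.

## Evaluation protocol

The evaluated universe is the unordered pairs {(i, j) : i < j}; self-pairs
are excluded (self-interaction is not a DDI), while the m² ordered-pair
accounting, diagonal included, is retained for dataset bookkeeping because
that is how the benchmark tables of record count pairs.

Each repeat draws a stratified k-fold split (k = 5) in which every fold's
positive count differs from exact proportionality by at most one pair.
Per fold: mask the test pairs out of Y → recompute GIP → re-run selection
and fusion → train on the training pairs → score the held-out pairs.
Selection and fusion are recomputed inside every fold because GIP is
fold-dependent. Precision, recall and F (harmonic mean, F = 2PR/(P+R))
are reported at the threshold maximizing F over all distinct scores plus
{0, 1} (ties to the lowest threshold); AUC gives tied scores half credit;
AUPR is the interpolation-free step-curve area (average precision). Fold
metrics are averaged within a repeat, then across repeats; the reported
standard deviation is taken over all fold×repeat values. F-measure
consistency with its own precision and recall holds per fold, not for the
aggregated means.

Label-permutation control: shuffling the upper-triangle entries of Y (and
re-symmetrizing) before the same cross-validated run must return AUC
statistically indistinguishable from 0.5; this guards against leakage
through GIP, fusion or fold construction.

## Synthetic benchmark

The generator plants the premise of similarity-based DDI prediction in its
simplest testable form. Defaults: m = 60 drugs in 4 latent clusters;
a symmetric compatibility relation over clusters drawn so compatible
cluster pairs cover 10–22% of the pair universe; pairs from compatible
clusters interact with probability 0.6, others 0.005, giving a prevalence
near 6–14% — the imbalance regime of curated DDI data. Three informative
views share the cluster structure but disagree on detail: within-cluster
similarity peaks at 0.9 and halves per step of rank distance along a
view-specific random circular ordering of the cluster, zero between
clusters, perturbed multiplicatively with Gaussian noise (sd 0.05) so
structural zeros stay zero. Two adversarial views exercise selection: a
uniform-noise view (off-diagonal 1/m, zero diagonal; row entropy exactly
log(m−1), always above the c1 cutoff for the supported sizes) and a
near-duplicate of the first informative view (additive noise sd 0.001;
affinity with its source far above c2).

Two quantitative constraints shaped these defaults. First, entropy: a row
spread uniformly over a 15-drug cluster already has entropy
ln 15 ≈ 2.71 > 0.6·ln 60 ≈ 2.46, so flat within-cluster similarity would
be rejected by the very filter the benchmark is meant to exercise; the
geometric decay concentrates rows below the cutoff with margin. Second,
the noise floor: with one score level per cluster pair, the best possible
AUC is limited by the mass of tied pairs, and interaction rates like
0.35/0.02 cap even the Bayes-optimal scorer near 0.83; the 0.6/0.005
rates raise that ceiling to ≈ 0.92–0.95, so a recovery bar of mean AUC
≥ 0.85 measures the pipeline rather than the generator.

What the benchmark does *not* emulate: real chemical fingerprints or
side-effect vocabularies, heavy-tailed drug degree distributions,
similarity views with different m or missing drugs, or correlated noise
between views. Passing it shows the pipeline recovers planted
block-structured signal under realistic imbalance; it says nothing about
performance on any particular curated dataset.

## Degenerate inputs and errors

All-zero Y (GIP bandwidth undefined), all-zero similarity rows at the
global-kernel stage, every-view-filtered selection, and single-class
training or metric inputs raise typed errors rather than returning
numbers. Asymmetric similarity files are averaged with a logged warning;
asymmetric interaction files are an error; nonzero interaction diagonals
are zeroed with a warning.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline on the
default 60-drug benchmark (1 770 unordered pairs, 5-fold CV, five
generator seeds plus three permutation controls) and on a 24-drug variant
for integration checks; both complete in about a minute each on one CPU
core. Larger panels scale as O(m²) memory for matrices and O(m²·epochs)
time for training.

## Known limitations

- The classifier is plain numpy on CPU; panels beyond a few thousand
  drugs will be slow, and no GPU path is provided.
- With a single input view the fusion stage is the identity, so the
  method reduces to GIP-augmented nearest-neighbour features plus the
  classifier.
- Whether the m² ordered-pair accounting or the unordered-pair universe is
  used for *training* changes the effective sample weighting; this
  implementation trains on both orderings of each unordered pair, which
  matches the m² bookkeeping up to the excluded diagonal.
- The entropy filter is scale-sensitive through row normalization only;
  views whose information lives in a global additive offset are judged
  uniform and removed.
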