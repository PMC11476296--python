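# Methods

## The prediction problem

Protamine identification from primary sequence is cast as binary
classification: given an amino-acid sequence over the 20-letter standard
alphabet, return YES (protamine) or NO with a probability score.  The
discriminative signal is compositional and order-based — protamines are
short and dominated by arginine — so the feature representation is a
fixed-length descriptor of composition plus short-range sequence-order
correlation.

## PseAAC featurization

Type-I pseudo amino acid composition with lag count λ and weight w.  For a
sequence of length L:

- f_u = n_u / L for the 20 residues (alphabetical one-letter order);
- θ_k = (1/(L−k)) Σ_{i=1..L−k} Θ(R_i, R_{i+k}) for k = 1..λ, where Θ is the
  mean squared difference of three standardised physicochemical scales
  (hydrophobicity, hydrophilicity, side-chain mass — Chou's web-server
  values, as shipped by the propy3 descriptor library);
- joint normalisation by D = 1 + w Σ_k θ_k gives components
  x_u = f_u/D and x_{20+k} = w θ_k/D, so the vector is non-negative and
  sums to exactly 1.

Parameters: λ = 10 (30 components) and w = 0.05 by default, both
configurable.  Each scale is standardised to zero mean and unit
*population* SD over the 20 residues; no intermediate rounding is applied,
so the normalisation identities hold to machine precision.  Validation
requires length ≥ λ + 1 — one residue pair must exist at the largest lag —
and rejects non-standard residues (B, J, O, U, X, Z) with a logged skip
rather than silently substituting them, because the property scales are
undefined there.  Homopolymers have θ_k = 0 for all k and therefore exactly
one nonzero component.

Degenerate inputs: featurization of a record set where every record fails
validation is an error; partial failure yields a skip list that callers
(and the CLI) surface.

## Synthetic benchmark generator

The generator emulates a curated protamine/non-protamine collection so the
whole pipeline is testable without any external download.  Positives are
short sequences (default length 25–60) with residues drawn i.i.d.:
arginine with probability `pos_arg_fraction` (default 0.45) and the
remainder weighted towards S, K, C, G and V (weights 6/5/4/3/3, all other
residues 0.5), mirroring the serine/lysine/cysteine enrichment of real
protamines.  At the default, the runner-up residue frequency is ≈ 0.12, so
arginine sits roughly three-fold above every other residue — the
compositional signature seen in position-frequency heatmaps of curated
protamines.  Negatives (default length 50–300) follow the Swiss-Prot
average composition; a mildly non-uniform background avoids a degenerate
benchmark that a single frequency threshold would solve.  Default class
sizes are 221 positives / 431 negatives, the imbalance the balancers are
designed around.

What the generator does **not** emulate: positional structure (real
protamines carry arginine *clusters*, not exchangeable positions),
phylogenetic correlation between sequences, and label noise.  Passing the
benchmark therefore demonstrates pipeline correctness and the mechanics of
augmentation/evaluation, not field performance on curated data: the
simulated classes are linearly separable in PseAAC space by construction,
which is also why every registry algorithm is expected to clear 0.9 test
accuracy on it.

The position-frequency matrix operation uses per-position coverage
denominators over ragged lengths, so each covered column sums to 100%;
positions are reported 1-based.

## Class balancing

**SMOTE** (native implementation): each synthetic row is
x + u·(x_nn − x), u ~ Uniform(0,1), with x a uniformly drawn minority row
and x_nn one of its k = 5 Euclidean nearest minority neighbours (neighbour
search via scikit-learn).  Interpolation never leaves the minority's
per-feature range.  The only strategy is balance-to-majority; balanced
input is returned unchanged.

**Tabular GAN** (NumPy implementation with explicit forward/backward
passes): generator 100-d Gaussian noise → 128 → 128 → out_dim (linear
output), discriminator out_dim → 128 → 128 → 1 (sigmoid); LeakyReLU
(α = 0.01) and dropout (0.5) on hidden layers; both networks trained with
Adam (lr 2e-4, β₁ 0.5, β₂ 0.999) on binary cross-entropy.  One epoch is one
shuffled pass of batch-30 minibatches over the real minority rows; per
minibatch the discriminator takes one update on real-vs-generated rows,
then the generator one update through the frozen discriminator with target
1.  Dropout is active only in the network currently being updated.  Design
choices where the architecture leaves room: noise dimension 100 (standard
practice), linear generator output with post-hoc clipping to [0, 1]
(features live there anyway), weight init N(0, 0.02), and 3-decimal
rounding applied at sampling time only — real rows are never touched.
Sampled rows are **not** guaranteed to sum to 1 like genuine PseAAC
vectors; they mimic the feature distribution, with visibly greater
dispersion, which the PCA QC view (`pca_compare`, components fitted on the
pooled real+synthetic matrix) is provided to inspect.  Balancing trains on
minority rows only; a non-finite loss aborts with a diagnostic.

The matrices involved are tiny, so 1000 epochs on a 221 × 30 table train in
well under a minute on one CPU core.  The point-mass recovery check
(training on identical rows pulls the generator's mean output towards that
row) passes with mean absolute error ≤ 0.12 at 400 epochs — a tolerance
calibrated from reference runs of this implementation.

## Evaluation protocol

80/20 train/test split (ceil ties to the training side; stratified by
default), stratified 10-fold cross-validation on the training side, and
eight classifier families addressed by name: LIGHTGBM, MLP, RF, XGBOOST,
KNN, LR, NB, RBF-SVM.  Hyperparameters are backend defaults, echoed into
every report; each stochastic backend receives the run seed.  Probability
scores come from the backend's `predict_proba` (the RBF-SVM is built with
Platt scaling enabled); a min-max-scaled decision function is the fallback
for score-only backends.  The decision threshold is 0.5 with ties going to
YES.  The CV summary is the unweighted fold mean.

Two leakage regimes are first-class and labelled in every report:

- `leaky`: each balancer is applied to the whole dataset *before* the
  split, so synthetic neighbours of test points can enter training — this
  reproduces the common augment-then-split protocol and inflates metrics;
- `safe`: the split comes first and balancing is fitted inside training
  folds (and on the final training set) only.

The inflation is asserted in the tests as a trend across ≥ 10 seeds, not
per seed, since individual splits are noisy.

## Metrics

Accuracy, recall (TPR), precision (PPV), F1, FPR, Cohen's κ
(Pe from the confusion-table marginals) and MCC are computed directly from
TP/FP/FN/TN.  Any zero-denominator ratio (precision with no positive
predictions, κ with Pe = 1, MCC with a zero marginal) returns 0 and is
flagged rather than raising, so degenerate CV folds never abort a run.
AUC is the Mann–Whitney rank statistic (mid-ranks under ties), which is
exact under tied scores and equals trapezoidal integration of the full ROC
sweep; step-curve points are emitted for plotting.

## Problem sizes in the test suite

The suite exercises the pipeline at sizes chosen to keep the default run
fast while preserving every contract: a 200+200-sequence benchmark for the
end-to-end classifier floors, 221 × 30 minority tables for the balancers
(the design imbalance), 1000 random confusion tables for the metric
oracle, and SMOTE geometry instances up to 50 × 5 where exhaustive
verification over all minority pairs is feasible.

## Known limitations

- The benchmark's i.i.d. residue model overstates separability relative to
  curated sequence collections; reported floors on it are contract checks,
  not performance claims.
- The GAN has no convergence diagnostics beyond its loss traces; mode
  collapse on multi-modal feature tables would have to be caught via the
  PCA QC view.
- Only type-I (non-amphiphilic) PseAAC is implemented; the exact property
  scales and weight w used by any particular published model are generally
  unverifiable, so agreement is pinned to this implementation's documented
  dialect via an independent oracle in the tests.
- Model bundles are serialised with joblib for convenience; no
  cross-version persistence guarantee is made.
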