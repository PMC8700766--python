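# Methods

This note documents the models and procedures implemented in
`tpecascade`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the package's numerical and
statistical conventions.

## Cascade ensemble

The model is a stack of layers, each holding the same multiset of base
learners given by the count vector `w = (w_RF, w_ET, w_Ada, w_GBDT)`,
`w_i ≥ 0`, `Σ w_i ≥ 1`.  Layer 1 consumes the original feature matrix;
every deeper layer consumes the original features concatenated with the
previous layer's class-probability block (one 2-column block per
learner), so its input width is `p + 2·Σ w_i`.  Only the immediately
preceding layer's probabilities are forwarded; probability blocks do not
accumulate across layers.

**Leak-free training augmentation.** The probability block a layer
contributes to *training* data is computed out-of-fold: the layer's
learner specifications are refitted on `k_inner` stratified folds
(default 3, 2 in the scaled test configurations) and each training row
receives probabilities from the fold model that did not see it.  For
inference the layer's learners are refitted once on the full layer input.
Without this, the augment block of a deep layer memorizes training
labels and the cascade overfits immediately.

**Depth growth.** Before growing, a stratified holdout (default 20%) is
split off the training partition with a seed derived from the model
seed.  Each trained layer is scored by soft-vote accuracy on that
holdout; growth stops after `patience` (default 1) consecutive
non-improvements or at `max_depth` (default 10), and the model is
truncated to the best-scoring depth (earliest on ties, preferring the
shallower model).  The growth history, including discarded layers, is
kept on the model for audit.  The retained layers are exactly those
trained on the growth partition — there is no post-selection refit on
the holdout — so the recorded validation accuracies describe precisely
the learners shipped in the model.  The outer evaluation's test fold is
never visible to any of this.

**Read-out.** Predicted scores are the mean of the final layer's
per-learner probability rows; the predicted label is the argmax, ties
broken toward the smaller class index.  Summing rather than averaging
changes nothing about the argmax; the normalized mean is kept so
`predict_proba` rows sum to 1.  The implementation is binary-only; the
class count is a module constant rather than an API parameter.

**Base families and defaults.** The four families are scikit-learn's
`RandomForestClassifier`, `ExtraTreesClassifier`, `AdaBoostClassifier`
and `GradientBoostingClassifier`.  Their hyperparameters are pinned in
`FAMILY_DEFAULTS` (100 trees for RF/ET/GBDT, 50 boosting rounds for
AdaBoost — the library defaults at the version pinned here, recorded
explicitly so a model file documents what was trained rather than
inheriting ambient library defaults).  Replicates of one family differ
only by seed, derived by a stable CRC32 hash of (model seed, family,
replicate index): reproducible across runs and platforms, distinct
across replicates.  The family registry is the extension point for
additional learners; the package deliberately ships exactly these four.

## TPE over the composition space

The search space is the integer grid `{0..max_count}^4` (default
`max_count` 8; observed useful compositions in practice stay well inside
this) with the all-zero vector excluded.  The loss is `1 − accuracy`
averaged over an internal stratified `k_tune`-fold split (default 3) of
the training partition.

Trials are split into *good* and *bad* at the γ quantile:
`n_good = max(1, ceil(γ·n))` lowest-loss trials, γ = 0.25.  Each
dimension gets a smoothed categorical density
`P(v) = (count(v) + b) / (n + b·(max_count+1))` with prior weight
`b = 1.0` — uniform in the no-data limit, proper for every trial set.
Proposals maximize the density ratio `l(x)/g(x)` (good over bad,
per-dimension product; the space is a flat 4-tuple, so the conditional
tree structure of the general method is vacuous).

The proposal rule has an exploitation stage ahead of density sampling:
if the incumbent (lowest-loss trial) has unevaluated one-step grid
neighbors, the neighbor with the best density ratio is proposed first;
otherwise 24 candidates are drawn from `l` and the best *unevaluated*
one by ratio is returned.  Two observations motivated this design on
discrete grids: re-proposing an already-evaluated vector carries no new
information when the objective is deterministic (duplicates are memoized
anyway), and sampling from a smoothed categorical density rarely lands
on the single best cell even when the density mode is correct — whereas
the cells adjacent to the incumbent are exactly where remaining
improvement is most likely.  On the separable quadratic benchmark
(optimum (2, 5, 5, 0), range 0..8, budget 60) this rule recovers the
exact optimum in 80/80 seeds, versus roughly half of seeds for
sampling-only proposals at the same settings, and clearly dominates
equal-budget random search in mean best loss.

The first `n_startup = 10` evaluations are seeded uniform draws.
Non-finite objective values are recorded as loss 1.0 and flagged.  The
whole optimizer is a pure function of (objective, config): identical
seeds give identical histories.

## Evaluation protocol

Metrics per run: precision TP/(TP+FP), recall TP/(TP+FN), F-measure
(harmonic mean, i.e. F1), accuracy (TP+TN)/n, and AUC as the
Mann–Whitney probability that a random positive outscores a random
negative with ties counting ½.  The positive class is label 1.  Metrics
with a vanishing denominator are reported as `None` with a named flag —
never silently zero — and excluded from aggregation.

The protocol is stratified k-fold CV repeated r times with seeded
partitions (defaults 10 × 10 = 100 runs); fold class proportions are
within one sample of the global proportion.  Reported values are means
of fold-level metrics over all runs.  Model comparisons reuse one set of
partitions for every model so per-run differences are paired; the paired
t-test is two-sided with significance marked at α = 0.05 and 0.01.
Degenerate difference vectors are flagged: all-zero gives t = 0, p = 1;
zero variance with nonzero mean is reported significant with p ≈ 0.

One caveat worth making explicit: per-run differences from *repeated*
CV are positively correlated (runs in different repeats share test
rows), which inflates the t-test's null rejection rate (measured ~9.5%
at nominal 5% in a 5×2 design).  The package's own null-calibration
check therefore uses a single repeat of 10 disjoint folds, where the
measured rejection rate is ~5%.  Comparisons on repeated-CV runs remain
useful for ranking but their p-values should be read as optimistic.

The benchmark grid contains the four single-family ensembles, the
fixed-composition cascade (`dem`: one learner of each family per layer,
no tuning), flat TPE-weighted soft voting (`tpe_voting`: one learner per
family, non-negative integer vote weights tuned by the same TPE
machinery — a reconstruction of the natural flat-voting counterpart, not
a reimplementation of any external system), and the tuned cascade
(`tpe_dem`).

## Preprocessing

Interval discretization maps a value `v` to the unique bin
`[c_i, c_{i+1})` with `c_0 = −∞` and the last interval unbounded — e.g.
age cuts (30, 60) produce bins (−∞, 30), [30, 60), [60, ∞).  Cut points
are configuration, not learned: the intended workflow is that domain
experts supply them.  An empty cut list is the single-bin identity.

Importance-based selection fits a seeded XGBoost classifier and keeps
columns whose *normalized* gain importance (summing to 1) exceeds the
threshold (default 0.01), preserving column order.  The threshold is on
the relative scale — this is stated in the output because a raw-scale
reading would select differently.  An empty selection raises an error
carrying the full importance table rather than silently returning
nothing.  Categorical inputs are label-encoded; all base learners are
tree models that split on the encoded integers, so one-hot expansion is
unnecessary.

## Synthetic data generator

`make_dataset` draws a latent standard-normal matrix, adds a mean shift
to informative columns for positive-class rows, and discretizes a
configurable fraction of columns into tertiles to create ordered
categorical features.  The shift vector's Euclidean norm equals
`signal_strength`, so the parameter is the Mahalanobis distance between
class centroids under identity covariance: 0 is pure noise (learner AUC
≈ 0.5), 2 is moderately learnable (the default), 3 gives a single forest
CV AUC above 0.9 on the 334-row profile.  Labels are laid out by exact
stratified construction and shuffled, so class counts match the profile
exactly for every seed, including the severe 55:803 imbalance profile.
Defaults: 40% categorical columns, 30% pure-noise columns, chosen as a
plausible mixed-type clinical table composition.

What this generator does *not* emulate: feature semantics and units,
correlated feature blocks, nonlinear or interaction-only signal, label
noise, and missingness.  Tests passing on this generator therefore
demonstrate the machinery (leak-freedom, protocol correctness, relative
model behavior under a known signal), not expected performance on any
real clinical table.

## Problem sizes used in tests and the acceptance script

Structural and statistical checks run at reduced ensemble sizes chosen
as the package's own trade-off between fidelity and turnaround: 5–15
trees per learner, cascade `max_depth` 2, `k_inner` 2, TPE budgets 3–8
with `max_count` 1–2 for model-level checks, and 3-fold single-repeat
CV for model comparisons.  The protocol checks that are about exact
structure (10 × 10 stratified CV, the quadratic TPE benchmark at budget
60 over 20 seeds, the 1,000-stack voting oracle, 200 null t-test
comparisons) run at full size.  None of the structural laws
(width arithmetic, composition invariance, stopping rule, split
conservation, density normalization) depend on ensemble size.

## Known limitations

- Binary classification only; the vote and augmentation generalize to k
  classes but are not exposed.
- Layer compositions are identical across layers by design; per-layer
  heterogeneous compositions are out of scope.
- The TPE optimizes only the four counts, not the base learners'
  continuous hyperparameters.
- Missing values are rejected, never imputed; imputation is upstream of
  this package.
- Model persistence uses joblib pickles: portable across runs of the
  pinned environment, not across arbitrary library versions.
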