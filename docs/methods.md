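# Methods

## Model

A hypergraph-based classifier is a fixed-size population of hyperedges.  A
hyperedge joins `l` miRNAs and `m` mRNAs and stores, for every stage `y`,
the stage-conditional mean vector, per-variable standard deviations (the
population, n-denominator estimator), and the full covariance of its
members, plus one weight `w(e_i|y)` per stage.  Only the SD diagonal enters
the matching distance; the full covariance is kept because the Gaussian
multivariate-MI estimator needs it.  The matching probability is a Gaussian
kernel `exp(−β·d)` on the normalized subdimensional distance `d`, with the
`1/|e_i|` normalizer outside the square root (the alternative placement is
a one-line change in `core_model.match_probability`).  Stage scores are
weighted sums of matching probabilities over the population; the posterior
is `logistic(c_y − mean_y' c_y')`.  The sigmoid is oriented so that more
evidence yields a larger posterior — the orientation consistent with
maximizing the conditional likelihood — and mean-centering makes the
posterior invariant to adding a constant to every stage score.  Exact ties
in the argmax prediction go to the first stage in the fixed (sorted) label
order, for reproducibility.

## Information measures

All estimators are moment-matched Gaussian closed forms on
ridge-regularized (`ε = 1e−6`) sample covariances: deterministic, fast, and
exact for the Gaussian synthetic data used throughout.  Per-gene MI with
the stage is `0.5·ln(var) − Σ_y p(y)·0.5·ln(var_y)` with variances floored
at `σ_min² = 1e−12` and negative estimates clamped to zero; an
equal-frequency-binning plug-in estimator (8 bins) is available via
`mi_backend="binning"`.  The total correlation of a member set is
`0.5·ln(Π var_i / det Σ)`, clamped at zero; the multivariate MI with the
class is the marginal total correlation minus its class-conditional
expectation under empirical class priors.  This difference is deliberately
*not* clamped: class-conditional dependence subtracts, giving
interaction-information-style negative values, and the ranking over
hyperedges still functions.

## Learning

Structure learning samples hyperedge members without replacement,
proportional to `I(X_i;Y)^η` within each block (miRNAs and mRNAs
separately).  The weighted draws use Gumbel-key (Efraimidis–Spirakis)
top-k sampling, which is distributed identically to successive weighted
draws without replacement but is vectorizable; member sets already present
in the population are rejected and resampled.  With
`pooled_selection=True` the two blocks are merged and only the total
degree `l + m` is fixed, the per-edge split floating — appropriate when the
miRNA/mRNA partition is nominal, as in the 7-variable verification dataset
whose two planted variable sets straddle the block boundary in
incompatible ways.  Per-gene MI vectors are computed once per training run
(they depend only on the data).  Fitted statistics and MMI values are
memoized per member set within a run — they too are functions of the data
only — so resampling a previously seen set costs nothing.

Initial weights are `κ·I(e_i) + Σ 1/σ²_{i|y}` (`κ` scales the MMI term
only, balancing it against the inverse variances).  Parameter learning is
batch gradient descent: every sample's posterior is computed with the
pre-update weights, per-sample deltas are summed over the epoch, and the
total is applied once; an online mode (`batch_updates=False`) applies each
sample's delta immediately.  The learning rate `γ` is constant (no decay).
Replacement removes the `⌈R_t·|H|⌉` hyperedges with the smallest
max-over-stages weight, where `R_t = (R_max − R_min)·e^(−t) + R_min`
decays from `R_max` at `t = 0` toward `R_min`.

Each training iteration runs the parameter epochs and then the
replacement, matching the published loop; because replacement can swap in
up to `R_min·|H|` freshly initialized hyperedges, training ends with one
extra block of parameter epochs so the returned model's weights are always
gradient-refined.  The trace records, per iteration, the population's mean
MMI (after replacement), the training accuracy (after the parameter
epochs), and the replacement ratio, plus the mean MMI of the initial
population as the structure-learning baseline.  All randomness flows from
a single seeded generator; identical seeds give identical models.

Defaults follow the published experimental settings: `l = 3`, `m = 5`,
`β = η = κ = γ = 1.0`, 100 structure epochs, 20 parameter epochs,
`R_max = 0.9`, `R_min = 0.5`, and 200 hyperedges per model.

## Synthetic data

`generate_threshold_rule_dataset` draws 7 independent `N(0, sd²)` variables and labels
each instance class 1 if `x2, x3, x4 > θ`, class 2 if `x5, x6, x7 < −θ`,
class 3 otherwise (defaults `sd = 1`, `θ = 2`).  The literal process is
extremely imbalanced — the class-1/2 probability is `(1−Φ(2))³ ≈ 1.18e−5`,
so a 500-instance draw is essentially all class 3 and cannot exercise a
classifier.  The balanced variant therefore draws the defining coordinates
of classes 1 and 2 from conditioned (truncated) normals to hit exact class
targets (default 100/100/300); both variants are exposed so the
discrepancy is inspectable.  The balanced variant is the verification
path.  Variables `x1–x3` play the miRNA role and `x4–x7` the mRNA role,
purely to exercise the paired-matrix interface.

`generate_planted_expression` produces stage-labelled miRNA/mRNA matrices:
background features are `N(0, noise_sd²)` in every stage; each planted
module's members get, in the module's stage only, a mean shift (miRNA
members −effect, mRNA members +effect — the repression motif) and share a
per-sample latent factor that replaces part of the noise, giving
within-module correlation (default 0.5) while keeping each member's total
variance at `noise_sd²`.  Keeping the variance flat matters: co-regulation
should alter the covariance structure, not make planted genes noisier than
background, otherwise the inverse-variance weight term penalizes exactly
the modules being planted.  What this generator does *not* emulate about
real expression data: heavy-tailed and count-derived noise, correlated
backgrounds, batch effects, and miRNA-target sparsity — passing tests show
the learner recovers Gaussian planted structure, not that it is robust to
those artifacts.

## Evaluation and test problem sizes

Cross-validation is stratified (required for rare stages to appear in
every fold) with a deterministic per-(repeat, fold) seed derivation; the
reported SD is the sample SD over the repeats' mean accuracies.  The k-NN
baseline (default `k = 3`, Euclidean, majority vote, vote ties broken by
smaller mean distance then label order) reuses the identical fold
structure for paired comparison.

The verification experiment uses the balanced 500-instance dataset with 20
hyperedges of 4 pooled variables and otherwise default settings, under 10
repetitions of 10-fold CV.  The planted-module experiments use 50 miRNAs ×
150 mRNAs, 60 samples per stage across two stages, two planted 3-member
modules (1 miRNA + 2 mRNAs each, effect size 3), and models of 60
hyperedges (`l = 2`, `m = 3`) trained for 50 structure × 10 parameter
epochs.  The large background pool is what gives structure learning
headroom: with a small pool, MI-biased sampling already concentrates the
initial population on planted features and the mean-MMI learning curve has
nowhere to climb.

## Known limitations

Per-stage statistics are unreliable for stages with few samples (the ridge
then dominates the conditional covariance; a warning is emitted when a
stage has fewer samples than a hyperedge has members plus one).  Batch
gradient accumulation over many samples with `γ = 1` can drive weights to
sigmoid saturation, after which updates vanish; the decaying replacement
schedule, not the gradient, is then the only driver of change.  The
duplicate-set rejection loop can exhaust when the requested population
approaches the number of distinct member sets; it raises after a bounded
number of tries.
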