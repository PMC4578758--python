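# Methods

## Problem setting

`hdboost` studies two-class prediction when the number of variables *p*
greatly exceeds the number of samples *n* — the regime of gene-expression
and other omics classifiers.  The central phenomenon is overfitting of the
base learner: a depth-capped CART tree with p ≥ 1000 and n ≈ 50 routinely
separates its training set perfectly even when the classes are identical
in distribution.  Boosting algorithms that steer their sample weights by
the training (resubstitution) error therefore receive a zero error signal,
freeze their weights, and collapse onto the base classifier.  The package
implements the algorithms needed to demonstrate, diagnose and repair this
failure mode.

## Algorithms

All ensembles use binary CART trees with a hard depth cap (1 = stump,
5 = "CART(5)"), `min_samples_split=2`, `min_samples_leaf=1`, Gini
impurity (classification) or weighted SSE (regression), and no pruning.
Only the depth cap regularizes: the trees must be *able* to shatter small
samples for the phenomenon under study to appear.  Split search is
delegated to scikit-learn's CART; fitted trees are extracted into plain
node arrays (`TreeModel`) so that prediction, serialization and reload are
self-contained and bit-reproducible.  Thresholds are midpoints between
consecutive sorted feature values and `x_j <= t` routes left; leaf-label
ties resolve toward class 1.

**AdaBoost.M1.**  Weights start uniform.  Per iteration: fit a weighted
tree, compute the weighted resubstitution error ε_m, set
α_m = ln((1−ε_m)/ε_m), multiply misclassified weights by e^{α_m},
renormalize.  Final label = weighted vote.  Boundary rules:

* ε_m = 0: α_m is computed at the clamped error δ = 1/(2n) and the weights
  are left unchanged.  Every subsequent stage then refits the identical
  tree, so the ensemble's predictions equal the single base tree's — the
  degeneracy this package exists to exhibit.
* ε_m ≥ ½: the stage receives α_m = 0 (no vote) and the weights are left
  unchanged.  We evaluated the alternative of resetting the weights to
  uniform and retrying; on the benchmark scenario it repeatedly erases the
  accumulated weight information and pins the ICV variant (below) at its
  base classifier's error, so the zero-vote rule was adopted.  For plain
  AdaBoost.M1 with tree learners the branch is essentially never taken.

**AdaBoost.M1.ICV.**  Identical recursion, but the per-sample error
indicators ε_m^i entering both ε_m = Σ w_i ε_m^i and the update
w_i ← w_i·e^{α_m ε_m^i} are estimated by internal k-fold cross-validation
(default k = 5): folds are stratified by class and re-randomized at every
boosting iteration; each fold model is a weighted tree fit on the
complementary folds under the current weights.  The stage classifier that
votes at prediction time is refit on the full weighted training set.
Because held-out error cannot collapse to zero under overfitting, the
weight dynamic survives where AdaBoost.M1's freezes.  ICV error estimates
hover near chance early on, so improvement is slow and many iterations
(several hundred) are typically needed.

**Gradient boosting (exponential loss).**  Labels are recoded to
ỹ ∈ {−1, +1}; the score starts at F₀ = ½·ln(n₂/n₁) (zero for balanced
data).  Per iteration a regression tree is fit to the pseudo-residuals
r_i = ỹ_i·e^{−ỹ_i F_i} and each leaf value is replaced by one Newton step
γ_j = Σ r_i / Σ |r_i| over the leaf's samples, capped at |γ| ≤ 8 for
numerical safety (the unconstrained minimizer is artanh of this ratio, so
the step is always a shortened move toward the optimum and the training
loss is provably non-increasing for ν ≤ 1).  The score update is
F ← F + ν·γ with shrinkage ν (default 1 = none, matching the finding that
shrinkage does not help plain gradient boosting in this regime).

**Stochastic gradient boosting.**  As above, with a fresh subsample of
⌊η·n⌋ samples drawn without replacement per iteration (default η = 0.5,
unstratified); the tree and its Newton steps use only the subsample while
the score update applies to all samples.  The mean decrease of the loss
on the out-of-bag samples is recorded per iteration; the OOB stopping
rule returns the iteration maximizing the cumulative sum of these
improvements.  Default shrinkage ν = 0.01.

**LogitBoost.**  Newton boosting of the binomial deviance: with
y* ∈ {0, 1} and p = 1/(1+e^{−2F}), working weights w_i = p_i(1−p_i)
(floored at 2·√ε_machine) and responses z_i = (y*_i−p_i)/w_i (clipped to
|z| ≤ 4) drive a weighted least-squares stump fit; F ← F + ½f_m.  The
floor and clip are the standard recommendations for this algorithm.

**Scores.**  For AUC, AdaBoost variants use the normalized vote margin
(Σα_m·±1)/Σα_m, gradient variants the additive score F, LogitBoost the
probability p (equivalently F, since p is monotone in F).  Class 2 is
predicted when the score is strictly positive; a zero margin resolves to
class 1.

## Synthetic data

`simulate_block_mvn` is the work-horse benchmark: multivariate normal
variables with unit variance, exchangeable correlation ρ (default 0.8)
within consecutive blocks of 10 variables and independence across blocks;
class 2 shifts the first `n_de` = 100 variables by μ₂ (default 0.7);
training sets are balanced (default n = 50) and test sets hold 500
samples per class.  The block factorization
x_j = √ρ·u_block + √(1−ρ)·e_j is exact and needs O(p) memory.  The DE
variables occupy the first columns and hence the first 10 blocks — their
placement is a modelling choice (correlated informative variables), as is
drawing a fresh test set per replicate.  `simulate_null_independent`
provides the no-signal iid control (true error 0.5) used to measure pure
overfitting, and `simulate_variance_shift` the "complex separation"
setting where classes share all means but 20 variables shrink their
variance fourfold in class 2 (one class nested in the other), which
linear-boundary stumps cannot express.

What the generator does *not* emulate: heavy-tailed or skewed expression
distributions, array-level batch effects, gene-length or intensity-
dependent variance, and correlated measurement noise.  Passing tests on
these benchmarks show the algorithms behave as designed under the stated
Gaussian block model, not that any particular error level will be attained
on real microarray data.

## Evaluation and selection

Metrics per classifier and iteration count: PA (overall accuracy), PA1 and
PA2 (class-specific), AUC (midrank-tied Mann–Whitney), g-means =
√(PA1·PA2), test error = 1 − PA.  `select_m_by_cv` pools held-out staged
predictions across stratified folds (with equal fold sizes this equals
averaging per-fold errors, and pooling keeps the curve's steps at 1/n) and
breaks ties toward the smallest iteration count; `select_m_oob` is the
cumulative-sum argmax of OOB improvements, unsmoothed.  Classifier panels
are compared by per-setting ranks of best g-means and two-sided paired
Wilcoxon signed-rank tests against a reference (exact null up to 25
settings, normal approximation beyond), Holm-adjusted, significant at
adjusted p < 0.05; all-zero difference vectors yield p = 1 by convention.

## Experiments and reproducibility

`run_experiment` derives one seed per replicate from the master seed
(`(seed·1000003 + r) mod (2³¹−1)`), generates train/test, fits the panel
and records staged metrics; execution is sequential and results are
independent of batching by construction.  Replicates that fail are skipped
and counted; more than 10 % failures aborts.  The real-data preprocessing
operators (variance pre-filter to the top-k columns, drop columns with
strictly more than 10 % missing values then zero-impute, majority-class
down-sizing inside each CV run) are exercised on synthetic fixtures only.

Problem sizes: the shipped benchmark scripts use 20–30 replicates of the
p = 1000 / n = 50 scenario and report means; at a test-set size of 1000
the standard error of a mean error over 20–30 replicates is roughly
0.01–0.02, which is sufficient to recover two-decimal error levels.  Unit
and property tests run at much smaller scale (tens of samples, ≤ tens of
iterations).

## Known limitations

* Exact split-for-split determinism of the tree engine under permutations
  of tied candidate splits follows scikit-learn's internal ordering (fixed
  `random_state`), not an explicit lowest-index rule; tests of split
  identity therefore use fixtures with unique optima.
* The ε ≥ ½ zero-vote rule and the 5-fold, per-iteration re-randomized,
  stratified ICV folds are design choices where the algorithm family
  admits variants; both are documented above and frozen for
  reproducibility.
* Only two-class problems and the exponential/binomial losses are
  supported; multiclass extensions and confidence-rated voting are out of
  scope.
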