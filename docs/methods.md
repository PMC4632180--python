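# Methods

## Problem and approach

The package performs wrapper feature selection for multiclass clinical
tabular data (the motivating setting is discriminating Normal / Mild
Cognitive Impairment / Alzheimer's Dementia from a few dozen
neuropsychological and imaging-derived measures).  The pipeline has
three phases:

1. **Base-classifier comparison** (`evalstats.compare_base_classifiers`)
   — candidate learner families (pruned binary-split decision tree,
   naive Bayes, random forest, RBF-kernel SVM) are cross-validated on
   the full data and again with a named key attribute removed, to pick a
   base classifier that stays sensitive when dominant attributes are
   absent.
2. **Subset search** (`pso.run_pso`) — binary particle-swarm
   optimisation over feature bit-masks.  Velocities follow
   `v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)` clamped to
   `±v_max`, and are mapped to bit probabilities through a sigmoid
   transfer.  Each visited subset is scored by a wrapper merit (below);
   every distinct evaluated subset enters a merit-sorted ranking.
3. **Merit merging** (`meritmerge.merit_merge`) — the ranking is walked
   top-down with three rules: equal-merit runs are evaluated
   individually and as a bitwise-OR union, the union kept only when its
   accuracy strictly improves (Case 1); when more than half the ranking
   ties at the top merit the search is re-run at the next higher
   iteration count, which favours smaller subsets and breaks the
   plateau (Case 2); when the next merit falls more than `delta` below
   the current one the walk stops (Case 3).  The selected subset is the
   accuracy-best candidate the walk evaluated, refit as the final
   bagged model.

## The merit functional

A subset `S` is scored as

    merit(S) = (1 - w) * cv_acc(S) + w * (1 - |S|/d),    w = 0.1,

where `cv_acc(S)` is the stratified 5-fold cross-validated mean accuracy
of a 10-member bagged ensemble of the search learner restricted to `S`
(majority vote, ties to the larger training prior then class-declaration
order).  The parsimony term is the standard formulation for swarm-based
wrapper selection.  It matters: with a raw-accuracy merit the search
plateaus on large subsets — adding a pure-noise column changes CV
accuracy by a few instances in either direction, so noise columns drift
in and out freely, rankings become walls of exact ties, and the
escalation rule fires on every run.  The weight 0.1 prices one feature
at `0.1/d` merit (at d = 20, about four training instances of
accuracy), enough to expel passengers without overriding any feature
that carries real signal.  `MeritEvaluator.accuracy` exposes the raw
accuracy component.

CV folds and the per-fold bootstrap resamples are fixed once per
(dataset, seed), so all subsets are scored on identical resamples —
differences between subsets are paired comparisons, not resampling
noise — and results are cached by mask, which the Case-2 re-runs
share.

## Base learners

Internals delegate to scikit-learn; the package owns configuration,
encodings and seed plumbing.

* `c45` — binary-split entropy tree. Pruning is realised as a minimum
  leaf size of 8 plus cost-complexity pruning (`ccp_alpha = 1e-3`);
  together these play the role of C4.5's error-based post-pruning with
  the pre-pruning additionally keeping trees small on noise-heavy
  subsets.  Missing cells need no imputation: sklearn trees route
  NaN-valued instances down both branches with proportional weights.
* `nb` — per-class Gaussian likelihoods for numeric columns and
  Laplace-smoothed (alpha = 1) frequencies for nominal columns,
  combined by summing log-likelihoods with the class prior counted
  once.
* `rf` — random forest, 600 trees by default (the out-of-bag error on
  data of this shape flattens by several hundred trees).
* `svm_rbf` — RBF-kernel SVM; `(C, gamma)` by grid search over the
  standard powers-of-two grid (C in 2^-5..2^15, gamma in 2^-15..2^3).
  Nominal features are one-hot encoded for the kernel space.

Every learner follows one prediction convention: `predict` is the
argmax of the normalised score rows, ties to the earlier-declared
class.  This makes the two code paths (labels vs scores) consistent by
construction.

## Synthetic data

`synthgen.generate` emulates the shape of a clinical three-class
extract: 750 instances (NL 200 / MCI 400 / AD 150), 48 features split
6 informative / 6 redundant / 36 noise, 5% cells missing completely at
random.  Informative feature `j` draws from `Normal(mu_cj, 1)` with
class means spaced `effect = 1.5` sd apart along a class ordering
permuted per feature, so no single feature orders the classes the same
way.  A redundant feature is one informative source plus
`Normal(0, 0.1)` — statistically almost interchangeable with its
source, which is deliberate: a minimal-subset selector should keep one
member of each such group and drop the rest, and tests phrase recovery
accordingly (coverage of each signal *group*, not of each labelled
column, once accuracy saturates).  The two-class variant defaults to
650 x 108 with counts NL 400 / AD 250 and a 12/12/84 feature split.

What the generator does **not** emulate: real score distributions
(bounded, skewed, discrete clinical scales), correlated noise between
measures, informative missingness, longitudinal structure.  Passing
recovery tests therefore show the machinery works under clean planted
signal, not that it meets clinical performance on real data.

## Evaluation

Multiclass metrics are one-vs-rest: per-class precision TP/(TP+FP),
recall TP/(TP+FN), per-class accuracy (TP+TN)/total, with the 0/0
convention mapping to 0.  AUC is the rank-statistic (Mann–Whitney) form
with ties counted one half; the multiclass summary is the unweighted
macro mean.  Press' Q for a classifier with `n` correct out of `m`
samples over `p` groups is `Q = (m - np)^2 / (m (p - 1))`, referred to
chi-square with 1 degree of freedom.  Protocols: stratified 5-fold CV
with pooled predictions (every instance predicted exactly once) or a
single stratified 70/30 train/test split.  Phase III evaluates walk
candidates and the final report under the same protocol and seed, so
the reported accuracy of the selected subset is exactly the accuracy
that selection saw, and is by construction at least the top-ranked
subset's.

## Preprocessing

Fixed order: drop features with more than 40% missing cells (strict
inequality), impute the rest class-wise (mean for numeric, mode for
nominal, ties by category declaration order, global fallback when a
class has no observed value), then rescale numeric columns — z-score
with the n-1 denominator by default, min-max to [0, 1] for columns
named in the configuration (which columns deserve [0, 1] scaling is
data-specific, so the pipeline takes an explicit list rather than
guessing).  Zero-variance columns map to zeros.

## Numerical and design choices

* Equal merit means within 1e-6: CV accuracies are exact rationals, so
  this separates genuine ties from float dust.
* "Much lower merit" (Case 3) defaults to an absolute drop of 0.05.
* The Case 2 escalation schedule is 60 → 80 → 100 iterations; when the
  tie survives the full schedule the walk proceeds with a warning flag.
* Accuracy ties in the final selection prefer fewer features, then walk
  order; merit ties in the ranking prefer fewer features, then the
  lexicographically smaller mask.
* All-zero particle positions are repaired by setting one uniformly
  random bit (an empty subset is unevaluable).
* Every stochastic component derives its seed from one global seed via
  `SeedSequence` spawn keys, so a single integer reproduces a full run
  byte for byte.
* Bagging uses B = 10 rounds by default; a bootstrap resample that
  loses all but one class is redrawn deterministically.
* pbest/gbest update only on strict merit improvement; the swarm
  initialises with Bernoulli(0.5) bits and velocities uniform in
  (-1, 1).

## Problem sizes used in the test suite

Wrapper search is expensive (each merit evaluation fits
`folds x B = 50` trees), so the suite exercises the full pipeline on
deliberately small instances: searches of 8–20 iterations with swarms
of 8–12 on 200–300 instances for unit tests, and the full 60-iteration,
swarm-30 configuration on the 300-instance, 10-feature benchmark where
the search is validated against exhaustive enumeration of all 1023
subsets.  The planted-recovery and no-signal studies run the complete
pipeline at n = 750 with reduced feature counts (d = 20 and d = 8).
These sizes are the package's choices for a fast, deterministic suite;
nothing in the implementation depends on them.

## Known limitations

* The redundant-feature construction makes informative/redundant pairs
  statistically interchangeable; recovery of the *labelled* informative
  set is therefore not identifiable once a near-copy exists, only
  coverage of each signal group.
* Case 1 merges whole equal-merit groups at once (pairwise-only merging
  is a possible alternative reading).
* The SVM path is supported but atypical as the Phase III evaluator and
  flagged in the decision log when used.
* With `train_test` protocol the walk selects on a single split;
  the default CV protocol is less exposed to split luck.
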