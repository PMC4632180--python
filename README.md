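# cpemm

Ensemble wrapper feature selection for multiclass clinical tabular
data: a binary particle-swarm search over feature subsets, scored by
bagged base-classifier cross-validation, consolidated by a three-case
*merit merge* procedure.

## The problem

Clinical diagnostic datasets — the motivating case is discriminating
Normal (NL), Mild Cognitive Impairment (MCI) and Alzheimer's Dementia
(AD) from a few dozen neuropsychological scores and imaging-derived
measures — mix a handful of genuinely informative attributes with
near-duplicate and irrelevant ones, imbalanced classes and missing
values.  The goal is a *minimal* feature subset that a classifier can
use to separate the classes, found by searching subset space rather
than ranking features one at a time.

## The method

A subset `S ⊆ {1..d}` is scored by the wrapper fitness

    merit(S) = 0.9 · cv_acc(S) + 0.1 · (1 − |S|/d)

where `cv_acc(S)` is the stratified 5-fold cross-validated accuracy of
a 10-member bagged ensemble (majority vote) of the base learner
restricted to `S`.  Binary PSO explores masks with the canonical
velocity rule `v ← w·v + c₁r₁(pbest − x) + c₂r₂(gbest − x)`
(w = 0.729, c₁ = c₂ = 1.49445, |v| ≤ 4) and sigmoid bit sampling.
Every visited subset enters a merit-sorted ranking, which the merge
phase walks top-down:

* **Case 1** — equal-merit subsets are evaluated individually and as
  their union; the union is kept only if it strictly improves accuracy.
* **Case 2** — if more than half the ranking ties at the top merit,
  the search re-runs at a higher iteration count (longer searches find
  smaller subsets).
* **Case 3** — a merit drop larger than δ = 0.05 terminates the walk.

The selected subset is the accuracy-best candidate evaluated during the
walk; it is refit as a bagged ensemble and reported with per-class
one-vs-rest accuracy/precision/recall, Mann–Whitney AUC, and Press' Q
significance `Q = (m − np)² / (m(p − 1)) ~ χ²(1)`.

## Worked example

```sh
cpemm synth --out demo.csv --seed 7 --truth-out truth.tsv
cpemm preprocess --in demo.csv --out clean.csv
cpemm run --in clean.csv --outdir results --iterations 12 --swarm-size 12 --seed 7
```

which prints

```
wrote 750x48 dataset (3 classes) to demo.csv
imputed missing cells with class-wise mean/mode
z-score normalised 48 numeric columns
wrote 750x48 dataset to clean.csv
selected 23 features; accuracy 0.9587
```

meaning the walk settled on a 23-feature subset whose 5-fold
cross-validated bagged-tree accuracy is 0.9587 (against a 0.533
majority-class baseline; a 12-iteration search on 48 features is a
quick demonstration — longer searches prune the subset much further).
`results/report.txt` contains the decision log (which merge case fired
at each step) and the per-class metric table;
`results/selected_features.txt` names the chosen columns, which on
synthetic data can be checked against `truth.tsv`'s planted informative
features.

The same pipeline is available as a library:

```python
from cpemm import (SyntheticSpec, generate, impute_classwise,
                   zscore_normalize, LearnerConfig, PSOConfig,
                   MergeConfig, cpemm)

data, truth = generate(SyntheticSpec(seed=7))
data = zscore_normalize(impute_classwise(data))
result = cpemm(data, LearnerConfig(kind="c45", seed=7))
print(result.selected.feature_names(data), result.report.overall_accuracy)
```

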