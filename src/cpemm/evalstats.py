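"""Evaluation: confusion-matrix metrics, one-vs-rest ROC/AUC, Press' Q,
cross-validation and train/test protocols, and the base-classifier
comparison with key-attribute ablation.

Multiclass metrics follow the one-vs-rest convention: per class c, TP =
instances of c predicted c, FP = non-c predicted c, FN = c predicted
non-c, TN = the rest.  Per-class "accuracy" is the one-vs-rest accuracy
(TP + TN) / total.  AUC is the Mann-Whitney probability that a random
positive outscores a random negative, ties counted one half.

Press' Q tests whether a classifier's correct-classification count n out
of m samples across p groups exceeds chance:

    Q = (m - n*p)^2 / (m*(p - 1)),   referred to chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from .dataio import Dataset
from .seeds import child_seed

__all__ = ["ConfusionMatrix", "EvaluationReport", "PressQResult",
           "accuracy", "precision", "recall", "ovr_accuracy", "roc_auc_ovr",
           "press_q", "kfold_cv", "train_test_eval", "compare_base_classifiers",
           "report_from_predictions"]


@dataclass
class ConfusionMatrix:
    """k x k count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix shape does not match class set")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_labels(cls, y_true: Sequence, y_pred: Sequence,
                    classes: Sequence[str]) -> "ConfusionMatrix":
        classes = tuple(classes)
        idx = {c: i for i, c in enumerate(classes)}
        k = len(classes)
        counts = np.zeros((k, k))
        for t, p in zip(y_true, y_pred):
            counts[idx[str(t)], idx[str(p)]] += 1
        return cls(counts=counts, classes=classes)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def _index(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise KeyError(f"unknown class {label!r}") from None

    def ovr(self, label: str) -> tuple[float, float, float, float]:
        """One-vs-rest (TP, FP, FN, TN) for a class."""
        i = self._index(label)
        tp = self.counts[i, i]
        fp = self.counts[:, i].sum() - tp
        fn = self.counts[i, :].sum() - tp
        tn = self.total - tp - fp - fn
        return float(tp), float(fp), float(fn), float(tn)


def accuracy(c: ConfusionMatrix) -> float:
    """Overall accuracy: correct classifications over all classifications."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(c.counts) / c.total)


def precision(c: ConfusionMatrix, label: str) -> float:
    """TP / (TP + FP); 0 when the class is never predicted."""
    tp, fp, _, _ = c.ovr(label)
    return tp / (tp + fp) if tp + fp > 0 else 0.0


def recall(c: ConfusionMatrix, label: str) -> float:
    """TP / (TP + FN); 0 when the class never occurs in the truth."""
    tp, _, fn, _ = c.ovr(label)
    return tp / (tp + fn) if tp + fn > 0 else 0.0


def ovr_accuracy(c: ConfusionMatrix, label: str) -> float:
    """(TP + TN) / total for the one-vs-rest collapse of a class."""
    tp, fp, fn, tn = c.ovr(label)
    return (tp + tn) / c.total


def roc_auc_ovr(scores: np.ndarray, y: Sequence, label: str,
                classes: Sequence[str]) -> float:
    """One-vs-rest AUC as the Mann-Whitney pair probability.

    ``scores`` is the (n, k) class-score matrix with columns in
    ``classes`` order; the column for ``label`` is the positive score.
    """
    classes = tuple(classes)
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([str(v) for v in y], dtype=object)
    j = classes.index(label)
    pos = scores[y == label, j]
    neg = scores[y != label, j]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both positive and negative instances for AUC")
    # rank-sum form of the Mann-Whitney statistic; midranks count ties 1/2
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


@dataclass
class PressQResult:
    m: int
    n: int
    p: int
    Q: float
    p_value: float


def press_q(m: int, n: int, p: int) -> PressQResult:
    """Press' Q significance statistic for a classifier's hit count.

    m samples, n correctly classified, p groups (classes).
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if p < 2:
        raise ValueError("Press' Q needs at least 2 groups")
    if not 0 <= n <= m:
        raise ValueError("n must lie in [0, m]")
    Q = (m - n * p) ** 2 / (m * (p - 1))
    return PressQResult(m=m, n=n, p=p, Q=float(Q),
                        p_value=float(stats.chi2.sf(Q, df=1)))


@dataclass
class EvaluationReport:
    """Pooled evaluation results under one protocol."""

    confusion: ConfusionMatrix
    protocol: str                      # "cv5" | "train_test"
    seed: int
    per_class: pd.DataFrame = field(default=None)  # Acc/Pre/Rec/AUC rows per class
    overall_accuracy: float = 0.0
    macro_auc: float | None = None

    def to_text(self) -> str:
        lines = [f"protocol\t{self.protocol}", f"seed\t{self.seed}",
                 f"overall_accuracy\t{self.overall_accuracy:.6f}"]
        if self.macro_auc is not None:
            lines.append(f"macro_auc\t{self.macro_auc:.6f}")
        lines.append("")
        lines.append(self.per_class.to_csv(sep="\t", float_format="%.6f"))
        return "\n".join(lines)


def report_from_predictions(y_true: Sequence, y_pred: Sequence,
                            classes: Sequence[str], protocol: str, seed: int,
                            scores: np.ndarray | None = None) -> EvaluationReport:
    """Assemble the per-class Acc/Pre/Rec (and AUC if scores given) table."""
    classes = tuple(classes)
    cm = ConfusionMatrix.from_labels(y_true, y_pred, classes)
    rows = {}
    aucs = []
    y_true_arr = np.asarray([str(v) for v in y_true], dtype=object)
    for c in classes:
        row = {"Acc": ovr_accuracy(cm, c), "Pre": precision(cm, c),
               "Rec": recall(cm, c)}
        if scores is not None and 0 < (y_true_arr == c).sum() < len(y_true_arr):
            row["AUC"] = roc_auc_ovr(scores, y_true_arr, c, classes)
            aucs.append(row["AUC"])
        rows[c] = row
    table = pd.DataFrame(rows).T
    return EvaluationReport(confusion=cm, protocol=protocol, seed=seed,
                            per_class=table, overall_accuracy=accuracy(cm),
                            macro_auc=float(np.mean(aucs)) if aucs else None)


FitPredict = Callable[[Dataset, np.ndarray], tuple[np.ndarray, np.ndarray | None]]
"""Callback: (training Dataset, test X) -> (labels, scores-or-None)."""


def stratified_fold_indices(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros((len(y), 1)), y.astype(str)))


def kfold_cv(d: Dataset, k: int = 5, fit_predict: FitPredict = None,
             seed: int = 0) -> EvaluationReport:
    """Stratified k-fold CV; each instance predicted exactly once; report pooled."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = d.y.astype(str)
    smallest = min(np.sum(y == c) for c in d.classes if np.any(y == c))
    if smallest < k:
        raise ValueError(f"smallest class has {smallest} < k={k} members")
    n = d.n_instances
    y_pred = np.empty(n, dtype=object)
    scores = None
    for tr, te in stratified_fold_indices(d.y, k, seed):
        train = Dataset(X=d.X[tr], y=d.y[tr], classes=d.classes, features=list(d.features))
        labels, s = fit_predict(train, d.X[te])
        y_pred[te] = labels
        if s is not None:
            if scores is None:
                scores = np.zeros((n, len(d.classes)))
            scores[te] = s
    return report_from_predictions(d.y, y_pred, d.classes, protocol=f"cv{k}",
                                   seed=seed, scores=scores)


def train_test_eval(d: Dataset, test_fraction: float = 0.3,
                    fit_predict: FitPredict = None, seed: int = 0) -> EvaluationReport:
    """Single stratified split; report on the held-out part only."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    idx = np.arange(d.n_instances)
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed,
                              stratify=d.y.astype(str))
    train = Dataset(X=d.X[tr], y=d.y[tr], classes=d.classes, features=list(d.features))
    labels, s = fit_predict(train, d.X[te])
    return report_from_predictions(d.y[te], labels, d.classes, protocol="train_test",
                                   seed=seed, scores=s)


# fewer-parameter ordering used to break comparison ties
_PARSIMONY = {"nb": 0, "c45": 1, "rf": 2, "svm_rbf": 3}


def compare_base_classifiers(d: Dataset, kinds: Sequence[str],
                             ablate: Sequence[str] = (), seed: int = 0,
                             folds: int = 5) -> tuple[pd.DataFrame, str]:
    """Cross-validate each learner kind on the full data and with named
    key attributes removed; return the condition table and the winner.

    The winner maximises mean overall accuracy across both conditions;
    ties go to the simpler model (nb < c45 < rf < svm_rbf).
    """
    from .learners import LearnerConfig, fit_base, predict, predict_scores

    if not kinds:
        raise ValueError("kinds must be non-empty")
    for name in ablate:
        d.column(name)  # raises if absent
    keep = np.array([f.name not in set(ablate) for f in d.features], dtype=bool)
    conditions = {"full": d}
    if len(ablate) > 0:
        conditions["ablated"] = Dataset(X=d.X[:, keep].copy(), y=d.y, classes=d.classes,
                                        features=[f for f, k in zip(d.features, keep) if k])
    else:
        conditions["ablated"] = d
    rows = []
    means: dict[str, list[float]] = {k: [] for k in kinds}
    for kind in kinds:
        for cond_name, cond in conditions.items():
            cfg = LearnerConfig(kind=kind, seed=child_seed(seed, "cmp", kind, cond_name))

            def fp(train: Dataset, X_test: np.ndarray):
                m = fit_base(cfg, train, np.ones(train.n_features, dtype=bool))
                return predict(m, X_test), predict_scores(m, X_test)

            rep = kfold_cv(cond, k=folds, fit_predict=fp, seed=child_seed(seed, "cv", kind, cond_name))
            row = {"kind": kind, "condition": cond_name,
                   "accuracy": rep.overall_accuracy, "macro_auc": rep.macro_auc}
            for c in d.classes:
                row[f"recall_{c}"] = rep.per_class.loc[c, "Rec"]
            rows.append(row)
            means[kind].append(rep.overall_accuracy)
    table = pd.DataFrame(rows)
    winner = max(kinds, key=lambda k: (np.mean(means[k]), -_PARSIMONY.get(k, 99)))
    return table, winner
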