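"""Uniform fit/predict/score contract over the four base-learner kinds.

The pipeline compares four classifier families on clinical tabular data:
a binary-split pruned decision tree (``c45``), naive Bayes (``nb``),
random forest (``rf``) and an RBF-kernel support vector machine
(``svm_rbf``).  Training internals delegate to scikit-learn; this module
owns the configuration surface, the feature-subset restriction, the
encoding of nominal features, seed plumbing, and a single prediction
convention: ``predict`` is the argmax of ``predict_scores`` with ties
broken by class-declaration order, for every learner kind.

Encoding rules:

* trees (``c45``, ``rf``) consume nominal category codes directly and,
  for ``c45``, tolerate missing cells (NaN) natively — instances with a
  missing value are routed down both branches with proportional weights,
  so tree data need not be imputed;
* ``nb`` models numeric features as per-class Gaussians and nominal
  features as per-class frequencies with Laplace smoothing (alpha = 1),
  combined by summing log-likelihoods;
* ``svm_rbf`` one-hot encodes nominal features into the numeric kernel
  space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import CategoricalNB, GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataio import Dataset

KINDS = ("c45", "nb", "rf", "svm_rbf")

__all__ = ["LearnerConfig", "FittedModel", "rbf_kernel", "fit_base",
           "predict", "predict_scores", "grid_search_svm", "KINDS"]


@dataclass(frozen=True)
class LearnerConfig:
    """Configuration for one base learner.

    ``ccp_alpha`` is the cost-complexity pruning strength of the c45
    tree (binary splits are implicit in the CART-style trees used);
    ``n_trees`` is the forest size, defaulting to 600 — the point where
    out-of-bag error typically flattens on data of this shape.
    """

    kind: str = "c45"
    ccp_alpha: float = 1e-3          # c45 post-pruning strength
    min_samples_leaf: int = 8        # c45 pre-pruning: minimum leaf size
    n_trees: int = 600               # rf forest size
    C: float = 1.0                   # svm_rbf margin penalty
    gamma: float = 0.1               # svm_rbf kernel width
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}; choose from {KINDS}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.ccp_alpha < 0:
            raise ValueError("ccp_alpha must be non-negative")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")


def rbf_kernel(xi: Sequence[float], xj: Sequence[float], gamma: float) -> float:
    """Gaussian radial-basis kernel exp(-gamma * ||xi - xj||^2)."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError("vectors must have equal length")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return float(np.exp(-gamma * np.sum((xi - xj) ** 2)))


class _MixedNB:
    """Naive Bayes over mixed columns: Gaussian numeric + categorical nominal.

    Class log-posteriors are the class log-prior plus the sum of the two
    blocks' log-likelihoods (conditional independence across all columns).
    """

    def __init__(self, num_idx: np.ndarray, nom_idx: np.ndarray,
                 n_categories: np.ndarray):
        self.num_idx = num_idx
        self.nom_idx = nom_idx
        self.n_categories = n_categories

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_MixedNB":
        classes, counts = np.unique(y, return_counts=True)
        self.classes_ = classes
        self.log_prior_ = np.log(counts / counts.sum())
        self.gnb_ = GaussianNB().fit(X[:, self.num_idx], y) if self.num_idx.size else None
        if self.nom_idx.size:
            self.cnb_ = CategoricalNB(alpha=1.0, min_categories=self.n_categories)
            self.cnb_.fit(X[:, self.nom_idx].astype(int), y)
        else:
            self.cnb_ = None
        return self

    def predict_log_proba_joint(self, X: np.ndarray) -> np.ndarray:
        # each sklearn joint log-likelihood already includes the class
        # log-prior once; keep it once when combining the two blocks
        parts = []
        if self.gnb_ is not None:
            parts.append(self.gnb_._joint_log_likelihood(X[:, self.num_idx]))
        if self.cnb_ is not None:
            parts.append(self.cnb_._joint_log_likelihood(X[:, self.nom_idx].astype(int)))
        total = parts[0]
        for p in parts[1:]:
            total = total + p - self.log_prior_[None, :]
        return total

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        log_post = self.predict_log_proba_joint(X)
        log_post -= log_post.max(axis=1, keepdims=True)
        p = np.exp(log_post)
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class FittedModel:
    """A trained base learner restricted to one feature subset."""

    kind: str
    estimator: object
    classes: tuple[str, ...]
    subset: np.ndarray                       # boolean mask over the full feature axis
    _encode: "callable"                      # maps raw subset columns -> estimator input
    _est_class_index: np.ndarray             # estimator class order -> dataset class order

    @property
    def n_subset_features(self) -> int:
        return int(self.subset.sum())


def _subset_matrix(d: Dataset, subset: np.ndarray) -> np.ndarray:
    subset = np.asarray(subset, dtype=bool)
    if subset.shape != (d.n_features,):
        raise ValueError("subset mask length does not match feature count")
    if not subset.any():
        raise ValueError("feature subset is empty")
    return d.X[:, subset]


def _onehot_encoder(d: Dataset, subset: np.ndarray):
    """Encoder mapping subset columns to a fully numeric matrix (one-hot nominal)."""
    metas = [m for m, s in zip(d.features, subset) if s]
    if all(m.kind == "numeric" for m in metas):
        return lambda A: A
    def enc(A: np.ndarray) -> np.ndarray:
        blocks = []
        for j, m in enumerate(metas):
            col = A[:, j]
            if m.kind == "numeric":
                blocks.append(col[:, None])
            else:
                k = len(m.categories)
                oh = np.zeros((len(col), k))
                ok = ~np.isnan(col)
                oh[np.where(ok)[0], col[ok].astype(int)] = 1.0
                blocks.append(oh)
        return np.hstack(blocks)
    return enc


def fit_base(cfg: LearnerConfig, d: Dataset, subset: np.ndarray | Sequence[bool]) -> FittedModel:
    """Train one base learner on the columns selected by ``subset``.

    Deterministic given ``cfg.seed``.  Data must be fully imputed except
    for ``c45``, which handles missing cells natively.
    """
    subset = np.asarray(subset, dtype=bool)
    A = _subset_matrix(d, subset)
    y = d.y.astype(str)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    has_nan = bool(np.isnan(A).any())
    if has_nan and cfg.kind != "c45":
        raise ValueError(f"{cfg.kind} requires imputed data (missing cells found)")

    metas = [m for m, s in zip(d.features, subset) if s]
    if cfg.kind == "c45":
        encode = lambda M: M
        est = DecisionTreeClassifier(criterion="entropy", ccp_alpha=cfg.ccp_alpha,
                                     min_samples_leaf=cfg.min_samples_leaf,
                                     random_state=cfg.seed)
    elif cfg.kind == "rf":
        encode = lambda M: M
        est = RandomForestClassifier(n_estimators=cfg.n_trees, criterion="entropy",
                                     random_state=cfg.seed, n_jobs=1)
    elif cfg.kind == "nb":
        encode = lambda M: M
        num_idx = np.array([j for j, m in enumerate(metas) if m.kind == "numeric"], dtype=int)
        nom_idx = np.array([j for j, m in enumerate(metas) if m.kind == "nominal"], dtype=int)
        n_cat = np.array([len(metas[j].categories) for j in nom_idx], dtype=int)
        est = _MixedNB(num_idx, nom_idx, n_cat)
    else:  # svm_rbf
        encode = _onehot_encoder(d, subset)
        est = SVC(kernel="rbf", C=cfg.C, gamma=cfg.gamma if cfg.gamma > 0 else "scale",
                  decision_function_shape="ovr", random_state=cfg.seed)

    est.fit(encode(A), y)
    est_classes = list(getattr(est, "classes_", d.classes))
    index = np.array([est_classes.index(c) for c in d.classes if c in est_classes], dtype=int)
    return FittedModel(kind=cfg.kind, estimator=est, classes=d.classes,
                       subset=subset, _encode=encode, _est_class_index=index)


def predict_scores(m: FittedModel, X: np.ndarray) -> np.ndarray:
    """Class-membership scores, one row per instance, rows summing to 1.

    Columns follow the dataset's class-declaration order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != m.n_subset_features:
        raise ValueError("instance table arity does not match the training subset")
    k = len(m.classes)
    if X.shape[0] == 0:
        return np.zeros((0, k))
    E = m._encode(X)
    est = m.estimator
    if m.kind == "svm_rbf":
        df = est.decision_function(E)
        if df.ndim == 1:                     # binary: distance to the boundary
            df = np.column_stack([-df, df])
        df -= df.max(axis=1, keepdims=True)
        raw = np.exp(df)
        raw /= raw.sum(axis=1, keepdims=True)
    else:
        raw = est.predict_proba(E)
    scores = np.zeros((X.shape[0], k))
    present = [c for c in m.classes if c in list(est.classes_)]
    cols = [m.classes.index(c) for c in present]
    scores[:, cols] = raw[:, m._est_class_index]
    # degenerate single-class estimator: give that class all the mass
    row_sums = scores.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    return scores / row_sums


def predict(m: FittedModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels: argmax of scores, ties to the earlier-declared class."""
    s = predict_scores(m, X)
    idx = np.argmax(s, axis=1)
    return np.array([m.classes[i] for i in idx], dtype=object)


def rf_oob_error(d: Dataset, n_trees: int, seed: int = 0) -> float:
    """Out-of-bag error of a random forest on the full feature set.

    The OOB estimate typically decreases with forest size and flattens
    once the forest is large enough (several hundred trees on data of
    this shape), which motivates the default ``n_trees``.
    """
    est = RandomForestClassifier(n_estimators=n_trees, criterion="entropy",
                                 oob_score=True, bootstrap=True,
                                 random_state=seed, n_jobs=1)
    est.fit(d.X, d.y.astype(str))
    return 1.0 - float(est.oob_score_)


DEFAULT_C_GRID = tuple(2.0 ** p for p in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** p for p in range(-15, 4, 2))


def grid_search_svm(d: Dataset, C_grid: Sequence[float] = DEFAULT_C_GRID,
                    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
                    folds: int = 5, seed: int = 0) -> tuple[float, float]:
    """Pick (C, gamma) maximising mean stratified-CV accuracy on the grid.

    Ties break toward smaller C, then smaller gamma.
    """
    from sklearn.model_selection import StratifiedKFold

    if not C_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    subset = np.ones(d.n_features, dtype=bool)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y = d.y.astype(str)
    best = None
    for C, gamma in itertools.product(sorted(C_grid), sorted(gamma_grid)):
        cfg = LearnerConfig(kind="svm_rbf", C=C, gamma=gamma, seed=seed)
        accs = []
        for tr, te in skf.split(d.X, y):
            sub = Dataset(X=d.X[tr], y=d.y[tr], classes=d.classes,
                          features=list(d.features))
            model = fit_base(cfg, sub, subset)
            accs.append(float(np.mean(predict(model, d.X[te]) == y[te])))
        score = float(np.mean(accs))
        if best is None or score > best[0] + 1e-12:
            best = (score, C, gamma)
    return best[1], best[2]
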