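"""Bootstrap-aggregated ensembles of a single base-learner kind.

Each ensemble member trains on a with-replacement resample of the
training data and the ensemble predicts by majority vote; ties break
toward the class with higher empirical frequency in the training data,
then class-declaration order.  Soft scores (for ROC) are the mean of the
member score rows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .dataio import Dataset
from .learners import FittedModel, LearnerConfig, fit_base, predict, predict_scores
from .seeds import child_seed

DEFAULT_BAG_SIZE = 10

__all__ = ["BaggedEnsemble", "bootstrap_sample", "fit_bagged", "majority_vote",
           "DEFAULT_BAG_SIZE"]


def bootstrap_sample(d: Dataset, seed: int) -> Dataset:
    """Draw ``n_instances`` rows i.i.d. with replacement; deterministic per seed."""
    if d.n_instances < 1:
        raise ValueError("cannot bootstrap an empty dataset")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.n_instances, size=d.n_instances)
    return Dataset(X=d.X[idx].copy(), y=d.y[idx].copy(), classes=d.classes,
                   features=list(d.features))


def majority_vote(votes: list[np.ndarray], class_priors: dict[str, float] | None = None,
                  classes: tuple[str, ...] | None = None) -> np.ndarray:
    """Plurality label per instance across equal-length label vectors.

    Ties break by higher ``class_priors`` value, then by position in
    ``classes`` (class-declaration order).
    """
    if not votes:
        raise ValueError("need at least one voter")
    votes = [np.asarray(v, dtype=object) for v in votes]
    n = len(votes[0])
    if any(len(v) != n for v in votes):
        raise ValueError("vote vectors must have equal length")
    if classes is None:
        classes = tuple(sorted({lbl for v in votes for lbl in v}))
    if n == 0:
        return np.empty(0, dtype=object)
    order = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((n, k))
    rows = np.arange(n)
    for v in votes:
        idx = np.fromiter((order[lbl] for lbl in v), dtype=int, count=n)
        counts[rows, idx] += 1.0
    priors = np.array([(class_priors or {}).get(c, 0.0) for c in classes])
    # prior bonus < 1 vote so it only resolves count ties; the 1e-9 term
    # favours earlier-declared classes and cannot override a real prior
    # difference (priors are multiples of 1/n_train, n_train << 1e6)
    score = counts + 0.5 * priors[None, :] + 1e-9 * (k - np.arange(k))[None, :]
    best = np.argmax(score, axis=1)
    return np.array([classes[i] for i in best], dtype=object)


@dataclass
class BaggedEnsemble:
    """Same-kind models fitted on bootstrap replicates, voting jointly."""

    members: list[FittedModel]
    base_cfg: LearnerConfig
    seed: int
    classes: tuple[str, ...]
    train_priors: dict[str, float]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        kinds = {m.kind for m in self.members}
        if len(kinds) != 1:
            raise ValueError("bagging uses classifiers of a single kind")

    @property
    def B(self) -> int:
        return len(self.members)

    @property
    def subset(self) -> np.ndarray:
        return self.members[0].subset

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = [predict(m, X) for m in self.members]
        return majority_vote(votes, self.train_priors, self.classes)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return np.mean([predict_scores(m, X) for m in self.members], axis=0)


def fit_bagged(cfg: LearnerConfig, d: Dataset, subset: np.ndarray, B: int = DEFAULT_BAG_SIZE,
               seed: int = 0) -> BaggedEnsemble:
    """Fit a ``B``-member bagged ensemble; member i's resample seed derives from (seed, i)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    subset = np.asarray(subset, dtype=bool)
    members = []
    for i in range(B):
        # a resample can, rarely, drop every member of a class; redraw
        # deterministically until at least two classes survive
        for attempt in range(16):
            boot = bootstrap_sample(d, child_seed(seed, "bootstrap", i, attempt))
            if len(set(boot.y)) >= 2:
                break
        member_cfg = dc_replace(cfg, seed=child_seed(seed, "member", i))
        members.append(fit_base(member_cfg, boot, subset))
    y = d.y.astype(str)
    priors = {c: float(np.mean(y == c)) for c in d.classes}
    return BaggedEnsemble(members=members, base_cfg=cfg, seed=seed,
                          classes=d.classes, train_priors=priors)
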