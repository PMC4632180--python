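"""Binary particle-swarm search over feature subsets (Phase II).

Each particle is a bit mask over the feature axis.  Velocities follow
the canonical update v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x),
clamped to +-v_max, and are mapped to bit probabilities through a
sigmoid transfer; an all-zero mask is repaired by setting one uniformly
random bit, since an empty subset cannot be scored.

A subset's merit is the standard wrapper fitness for swarm-based feature
selection: a weighted blend of predictive accuracy and parsimony,

    merit(S) = (1 - w) * cv_accuracy(S) + w * (1 - |S|/d),   w = 0.1,

where cv_accuracy is the stratified k-fold cross-validated mean accuracy
of a bagged base-classifier ensemble restricted to S.  The size term
supplies the selection pressure towards minimal subsets that a raw
accuracy score lacks — without it the search plateaus on large
equal-accuracy subsets that drag noise features along.  Merit evaluation
dominates the run time, so results are cached by mask; the cache may be
shared across searches on the same data (the merge phase re-runs the
search at higher iteration counts and reuses it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
import numpy as np

from .bagging import DEFAULT_BAG_SIZE, bootstrap_sample, majority_vote
from .dataio import Dataset
from .evalstats import stratified_fold_indices
from .learners import LearnerConfig, fit_base, predict
from .seeds import child_seed

__all__ = ["FeatureSubset", "PSOConfig", "SwarmState", "SubsetRanking",
           "MeritEvaluator", "merit", "sigmoid_transfer", "init_swarm",
           "pso_step", "run_pso", "write_ranking", "read_ranking"]


@dataclass
class FeatureSubset:
    """A binary inclusion mask over features with an attached merit score."""

    mask: np.ndarray
    merit: float | None = None
    origin: str = "manual"            # "pso" | "merged" | "manual"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.merit is not None and not 0.0 <= self.merit <= 1.0:
            raise ValueError("merit must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return int(self.mask.sum())

    @property
    def mask_string(self) -> str:
        return "".join("1" if b else "0" for b in self.mask)

    def feature_names(self, d: Dataset) -> list[str]:
        return [f.name for f, b in zip(d.features, self.mask) if b]


def _ranking_key(s: FeatureSubset):
    # best first: higher merit, then fewer features, then lexicographic mask
    return (-s.merit, s.n_features, s.mask_string)


@dataclass
class SubsetRanking:
    """Deduplicated subsets in non-increasing merit order."""

    subsets: list[FeatureSubset]
    gbest_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        merits = [s.merit for s in self.subsets]
        if any(m is None for m in merits):
            raise ValueError("ranked subsets must carry a merit")
        if any(a < b for a, b in zip(merits, merits[1:])):
            raise ValueError("merits must be non-increasing")
        if len({s.mask_string for s in self.subsets}) != len(self.subsets):
            raise ValueError("ranked masks must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.subsets)

    @property
    def best(self) -> FeatureSubset:
        return self.subsets[0]


@dataclass(frozen=True)
class PSOConfig:
    """Search hyper-parameters.

    The iteration count is typically run in the 60-100 range: longer
    searches find smaller subsets of equal merit.  Inertia and the two
    acceleration constants default to the constriction-style values
    w = 0.729, c1 = c2 = 1.49445 standard for binary PSO.
    """

    iterations: int = 60
    swarm_size: int = 30
    inertia: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    v_max: float = 4.0
    top_k: int = 20
    merit_folds: int = 5
    bag_size: int = DEFAULT_BAG_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.swarm_size < 1:
            raise ValueError("swarm_size must be >= 1")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")


def sigmoid_transfer(v: float | np.ndarray) -> float | np.ndarray:
    """Logistic transfer mapping a velocity to a bit probability."""
    return 1.0 / (1.0 + np.exp(-v))


DEFAULT_SIZE_WEIGHT = 0.1


class MeritEvaluator:
    """Scores feature subsets by bagged-ensemble cross-validation.

    ``merit(mask)`` returns the size-penalised wrapper fitness;
    ``accuracy(mask)`` exposes the raw CV-accuracy component.  Fold
    splits and the per-fold bootstrap resamples depend only on the
    dataset and seed, so they are materialised once; scoring a subset
    then costs ``folds * B`` base-learner fits on pre-sliced data.
    Scores are cached by mask bytes.
    """

    def __init__(self, d: Dataset, learner: LearnerConfig, folds: int = 5,
                 B: int = DEFAULT_BAG_SIZE, seed: int = 0,
                 size_weight: float = DEFAULT_SIZE_WEIGHT):
        if not 0 <= size_weight < 1:
            raise ValueError("size_weight must be in [0, 1)")
        self.size_weight = size_weight
        if d.n_instances < folds:
            raise ValueError("fewer instances than folds")
        self.d = d
        self.learner = learner
        self.folds = folds
        self.B = B
        self.seed = seed
        self.cache: dict[bytes, float] = {}
        self.n_evaluations = 0  # cache misses, i.e. actual CV runs
        self._fixtures = []
        # trees consume category codes directly, so for them the whole CV
        # fixture can be pre-encoded once as float32/int arrays and each
        # subset scored without re-wrapping datasets; the generic path and
        # the encoded path produce identical predictions
        self._fast = learner.kind == "c45"
        # input validation can be skipped on the hot path only when no
        # missing cells are present (NaN routing is wired up during checks)
        self._check_input = bool(np.isnan(d.X).any())
        code = {c: i for i, c in enumerate(d.classes)}
        for f, (tr, te) in enumerate(stratified_fold_indices(d.y, folds, child_seed(seed, "folds"))):
            train = Dataset(X=d.X[tr], y=d.y[tr], classes=d.classes,
                            features=list(d.features))
            fold_seed = child_seed(seed, "fold", f)
            boots = []
            for i in range(B):
                for attempt in range(16):
                    boot = bootstrap_sample(train, child_seed(fold_seed, "bootstrap", i, attempt))
                    if len(set(boot.y)) >= 2:
                        break
                member_seed = child_seed(fold_seed, "member", i)
                if self._fast:
                    yb = np.fromiter((code[v] for v in boot.y), dtype=np.intp,
                                     count=len(boot.y))
                    boots.append((boot.X.astype(np.float32), yb, member_seed))
                else:
                    boots.append((boot, member_seed))
            y_train = train.y.astype(str)
            priors = {c: float(np.mean(y_train == c)) for c in d.classes}
            if self._fast:
                k = len(d.classes)
                priors_vec = np.array([priors[c] for c in d.classes])
                bonus = 0.5 * priors_vec + 1e-9 * (k - np.arange(k))
                yte = np.fromiter((code[v] for v in d.y[te]), dtype=np.intp,
                                  count=len(te))
                self._fixtures.append((boots, bonus, d.X[te].astype(np.float32), yte))
            else:
                self._fixtures.append((boots, priors, d.X[te], d.y[te].astype(str)))

    def accuracy(self, mask: np.ndarray) -> float:
        """Raw CV-accuracy component of the merit, in [0, 1]."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("cannot score an empty subset")
        key = mask.tobytes()
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        self.n_evaluations += 1
        value = self._merit_fast(mask) if self._fast else self._merit_generic(mask)
        self.cache[key] = value
        return value

    def merit(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        acc = self.accuracy(mask)
        w = self.size_weight
        return (1 - w) * acc + w * (1 - mask.sum() / len(mask))

    def _merit_generic(self, mask: np.ndarray) -> float:
        accs = []
        for boots, priors, X_test, y_test in self._fixtures:
            votes = []
            for boot, member_seed in boots:
                cfg = dc_replace(self.learner, seed=member_seed)
                model = fit_base(cfg, boot, mask)
                votes.append(predict(model, X_test[:, mask]))
            pred = majority_vote(votes, priors, self.d.classes)
            accs.append(float(np.mean(pred == y_test)))
        return float(np.mean(accs))

    def _merit_fast(self, mask: np.ndarray) -> float:
        from sklearn.tree import DecisionTreeClassifier

        lc = self.learner
        k = len(self.d.classes)
        check = self._check_input
        accs = []
        for boots, bonus, X_test, y_test in self._fixtures:
            T = X_test[:, mask]
            counts = np.zeros((len(y_test), k))
            rows = np.arange(len(y_test))
            for Xb, yb, member_seed in boots:
                clf = DecisionTreeClassifier(criterion="entropy", ccp_alpha=lc.ccp_alpha,
                                             min_samples_leaf=lc.min_samples_leaf,
                                             random_state=member_seed)
                clf.fit(Xb[:, mask], yb, check_input=check)
                counts[rows, clf.predict(T, check_input=check).astype(np.intp)] += 1.0
            pred = np.argmax(counts + bonus[None, :], axis=1)
            accs.append(float(np.mean(pred == y_test)))
        return float(np.mean(accs))


def merit(subset: FeatureSubset | np.ndarray, d: Dataset, cfg: LearnerConfig,
          folds: int = 5, seed: int = 0, B: int = DEFAULT_BAG_SIZE,
          size_weight: float = DEFAULT_SIZE_WEIGHT) -> float:
    """Wrapper merit of one subset: size-penalised stratified CV accuracy
    of the bagged ensemble restricted to it.  Deterministic given ``seed``."""
    mask = subset.mask if isinstance(subset, FeatureSubset) else np.asarray(subset, dtype=bool)
    return MeritEvaluator(d, cfg, folds=folds, B=B, seed=seed,
                          size_weight=size_weight).merit(mask)


@dataclass
class SwarmState:
    positions: np.ndarray             # (P, d) bool
    velocities: np.ndarray            # (P, d) float
    pbest: list[FeatureSubset]
    gbest: FeatureSubset
    iteration: int
    rng: np.random.Generator
    visited: dict[bytes, FeatureSubset] = field(default_factory=dict)


def _repair_zero_rows(positions: np.ndarray, rng: np.random.Generator) -> None:
    empty = ~positions.any(axis=1)
    for i in np.where(empty)[0]:
        positions[i, rng.integers(0, positions.shape[1])] = True


def _record(state_visited: dict, mask: np.ndarray, m: float) -> FeatureSubset:
    key = mask.tobytes()
    sub = state_visited.get(key)
    if sub is None or m > sub.merit:
        sub = FeatureSubset(mask=mask.copy(), merit=m, origin="pso")
        state_visited[key] = sub
    return sub


def init_swarm(d: Dataset, cfg: PSOConfig, evaluator: MeritEvaluator) -> SwarmState:
    """Uniform-random swarm: Bernoulli(0.5) bits, velocities in (-1, 1)."""
    rng = np.random.default_rng(child_seed(cfg.seed, "swarm"))
    P = cfg.swarm_size
    positions = rng.random((P, d.n_features)) < 0.5
    _repair_zero_rows(positions, rng)
    velocities = rng.uniform(-1.0, 1.0, size=(P, d.n_features))
    visited: dict[bytes, FeatureSubset] = {}
    pbest = []
    for i in range(P):
        m = evaluator.merit(positions[i])
        pbest.append(_record(visited, positions[i], m))
    gbest = min(pbest, key=_ranking_key)
    return SwarmState(positions=positions, velocities=velocities, pbest=list(pbest),
                      gbest=gbest, iteration=0, rng=rng, visited=visited)


def pso_step(state: SwarmState, cfg: PSOConfig, evaluator: MeritEvaluator) -> SwarmState:
    """Advance the swarm one iteration in place and return it."""
    P, dim = state.positions.shape
    x = state.positions.astype(float)
    pb = np.vstack([s.mask for s in state.pbest]).astype(float)
    gb = state.gbest.mask.astype(float)[None, :]
    r1 = state.rng.random((P, dim))
    r2 = state.rng.random((P, dim))
    v = (cfg.inertia * state.velocities
         + cfg.c1 * r1 * (pb - x)
         + cfg.c2 * r2 * (gb - x))
    np.clip(v, -cfg.v_max, cfg.v_max, out=v)
    state.velocities = v
    state.positions = state.rng.random((P, dim)) < sigmoid_transfer(v)
    _repair_zero_rows(state.positions, state.rng)
    for i in range(P):
        m = evaluator.merit(state.positions[i])
        sub = _record(state.visited, state.positions[i], m)
        if m > state.pbest[i].merit:
            state.pbest[i] = sub
        if m > state.gbest.merit:
            state.gbest = sub
    state.iteration += 1
    return state


def run_pso(d: Dataset, cfg: PSOConfig, learner: LearnerConfig,
            evaluator: MeritEvaluator | None = None) -> SubsetRanking:
    """Run the full search and rank every distinct subset it evaluated.

    Ties in merit rank the smaller subset first, then the
    lexicographically smaller mask.  The ranking is truncated to
    ``cfg.top_k`` entries; ``gbest_trace`` records the best merit after
    each iteration (non-decreasing by construction).
    """
    if evaluator is None:
        evaluator = MeritEvaluator(d, learner, folds=cfg.merit_folds,
                                   B=cfg.bag_size, seed=child_seed(cfg.seed, "merit"))
    state = init_swarm(d, cfg, evaluator)
    trace = [state.gbest.merit]
    for _ in range(cfg.iterations):
        state = pso_step(state, cfg, evaluator)
        trace.append(state.gbest.merit)
    ranked = sorted(state.visited.values(), key=_ranking_key)[: cfg.top_k]
    return SubsetRanking(subsets=ranked, gbest_trace=trace)


# ---------------------------------------------------------------------
# ranking serialisation (tab-separated text)
# ---------------------------------------------------------------------

def write_ranking(r: SubsetRanking, path) -> None:
    lines = ["mask\tmerit\tn_features\torigin"]
    for s in r.subsets:
        lines.append(f"{s.mask_string}\t{s.merit:.10f}\t{s.n_features}\t{s.origin}")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")


def read_ranking(path) -> SubsetRanking:
    from pathlib import Path
    lines = Path(path).read_text().splitlines()
    subs = []
    for line in lines[1:]:
        if not line.strip():
            continue
        mask_s, merit_s, _n, origin = line.split("\t")
        subs.append(FeatureSubset(mask=np.array([c == "1" for c in mask_s]),
                                  merit=float(merit_s), origin=origin))
    return SubsetRanking(subsets=subs)
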