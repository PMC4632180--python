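"""Merit Merge consolidation of ranked feature subsets (Phase III) and
the one-call CPEMM pipeline.

The merge walks the merit-sorted subset list top-down and evaluates
candidate subsets with the base classifier under the reporting protocol
(default 5-fold CV with a bagged ensemble), applying three rules:

* Case 1 — a maximal run of equal-merit subsets is evaluated member by
  member and as one merged (bitwise-OR) subset; the merged subset is
  kept only if its accuracy strictly exceeds the best individual's,
  otherwise the individuals stand.
* Case 2 — if more than half of the ranking ties at the top merit the
  search is re-run at the next higher iteration count (the longer search
  favours smaller subsets and breaks the tie); when the iteration
  schedule is exhausted with the tie unresolved the walk proceeds with a
  warning flag.
* Case 3 — when the next subset's merit drops more than ``delta`` below
  the current run's, the walk terminates: everything further down is
  noise.

The selected feature set is the accuracy-best subset among everything
the walk evaluated; accuracy ties prefer fewer features, then walk
order.  Every rule application is recorded in an audit log.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from functools import reduce
from typing import Callable

import numpy as np

from .bagging import BaggedEnsemble, DEFAULT_BAG_SIZE, fit_bagged
from .dataio import Dataset
from .evalstats import EvaluationReport, kfold_cv, train_test_eval
from .learners import LearnerConfig
from .pso import FeatureSubset, MeritEvaluator, PSOConfig, SubsetRanking, run_pso
from .seeds import child_seed

__all__ = ["MergeConfig", "Decision", "MergeResult", "merge_subsets",
           "merit_merge", "cpemm"]


@dataclass(frozen=True)
class MergeConfig:
    """Phase III knobs.

    ``equal_merit_tol`` defines "equal merit" (CV accuracies are exact
    rationals, so a tiny tolerance suffices); ``drop_threshold`` is the
    absolute merit drop read as "much lower"; ``iteration_schedule``
    lists the search lengths Case 2 may escalate through, the first
    entry being the initial search.
    """

    equal_merit_tol: float = 1e-6
    drop_threshold: float = 0.05
    top_tie_fraction: float = 0.5
    iteration_schedule: tuple[int, ...] = (60, 80, 100)
    protocol: str = "cv5"             # "cv5" | "train_test"
    test_fraction: float = 0.3
    eval_folds: int = 5
    bag_size: int = DEFAULT_BAG_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.drop_threshold <= 1:
            raise ValueError("drop_threshold must be in (0, 1]")
        if any(a >= b for a, b in zip(self.iteration_schedule, self.iteration_schedule[1:])):
            raise ValueError("iteration_schedule must be strictly increasing")
        if self.protocol not in ("cv5", "train_test"):
            raise ValueError("protocol must be cv5 or train_test")


@dataclass
class Decision:
    """One audit-log entry: which rule fired and on what."""

    case: str                          # "case1_merge" | "case1_individuals" |
                                       # "case2_rerun" | "case2_exhausted" |
                                       # "case3_stop" | "evaluate" | "selected" | "note"
    detail: str

    def __str__(self) -> str:
        return f"{self.case}: {self.detail}"


@dataclass
class MergeResult:
    selected: FeatureSubset
    selected_group: list[FeatureSubset]    # >1 entries for a Case-1 non-merged outcome
    evaluations: list[tuple[FeatureSubset, float]]
    decisions: list[Decision]
    final_model: BaggedEnsemble | None
    report: EvaluationReport | None
    ranking: SubsetRanking
    warning: bool = False


def merge_subsets(a: FeatureSubset, b: FeatureSubset) -> FeatureSubset:
    """Bitwise-OR union of two subsets; merit unset, origin 'merged'."""
    if a.mask.shape != b.mask.shape:
        raise ValueError("mask lengths differ")
    return FeatureSubset(mask=a.mask | b.mask, merit=None, origin="merged")


class _SubsetEvaluator:
    """Accuracy of a bagged base-classifier ensemble on one subset under
    the reporting protocol, cached by mask (reports kept for reuse)."""

    def __init__(self, d: Dataset, learner: LearnerConfig, cfg: MergeConfig):
        self.d = d
        self.learner = learner
        self.cfg = cfg
        self.seed = child_seed(cfg.seed, "eval")
        self.reports: dict[bytes, EvaluationReport] = {}

    def _fit_predict(self, mask: np.ndarray):
        def fp(train: Dataset, X_test: np.ndarray):
            ens = fit_bagged(self.learner, train, mask, B=self.cfg.bag_size,
                             seed=child_seed(self.seed, "bag"))
            return ens.predict(X_test[:, mask]), ens.predict_scores(X_test[:, mask])
        return fp

    def report(self, mask: np.ndarray) -> EvaluationReport:
        key = np.asarray(mask, dtype=bool).tobytes()
        rep = self.reports.get(key)
        if rep is None:
            if self.cfg.protocol == "cv5":
                rep = kfold_cv(self.d, k=self.cfg.eval_folds,
                               fit_predict=self._fit_predict(mask), seed=self.seed)
            else:
                rep = train_test_eval(self.d, test_fraction=self.cfg.test_fraction,
                                      fit_predict=self._fit_predict(mask), seed=self.seed)
            self.reports[key] = rep
        return rep

    def __call__(self, mask: np.ndarray) -> float:
        return self.report(mask).overall_accuracy


def _names(s: FeatureSubset, d: Dataset | None) -> str:
    if d is None:
        return s.mask_string
    return "{" + ",".join(s.feature_names(d)) + "}"


def merit_merge(r: SubsetRanking, d: Dataset | None, learner: LearnerConfig | None,
                cfg: MergeConfig,
                rerun: Callable[[int], SubsetRanking] | None = None,
                accuracy_fn: Callable[[np.ndarray], float] | None = None) -> MergeResult:
    """Consolidate a merit ranking into one selected feature set.

    ``rerun(iterations)`` re-executes the subset search at a higher
    iteration count for Case 2.  ``accuracy_fn`` overrides the default
    bagged-CV subset evaluator (used by tests to probe the case logic);
    when given, no final model or report is fitted.
    """
    if len(r) == 0:
        raise ValueError("ranking is empty")
    decisions: list[Decision] = []
    warning = False
    evaluator = None
    if accuracy_fn is None:
        if d is None or learner is None:
            raise ValueError("need data and a learner unless accuracy_fn is given")
        if learner.kind == "svm_rbf":
            decisions.append(Decision("note", "svm_rbf as the evaluation classifier is "
                                      "allowed but atypical for this pipeline"))
        evaluator = _SubsetEvaluator(d, learner, cfg)
        accuracy_fn = evaluator

    # ---- Case 2: top-tie escalation -------------------------------
    ranking = r
    sched_i = 1                                   # schedule[0] = the initial search
    while True:
        merits = [s.merit for s in ranking.subsets]
        ties = sum(1 for m in merits if abs(m - merits[0]) <= cfg.equal_merit_tol)
        if len(merits) > 1 and ties > cfg.top_tie_fraction * len(merits):
            if rerun is not None and sched_i < len(cfg.iteration_schedule):
                iters = cfg.iteration_schedule[sched_i]
                sched_i += 1
                decisions.append(Decision(
                    "case2_rerun",
                    f"{ties}/{len(merits)} subsets tie at top merit {merits[0]:.6f}; "
                    f"re-running search at {iters} iterations"))
                ranking = rerun(iters)
                continue
            warning = True
            decisions.append(Decision(
                "case2_exhausted",
                f"{ties}/{len(merits)} subsets still tie at the top after the full "
                f"iteration schedule; proceeding with the best found so far"))
        break

    # ---- walk the ranking -----------------------------------------
    subs = ranking.subsets
    evaluations: list[tuple[FeatureSubset, float]] = []
    i = 0
    while i < len(subs):
        j = i + 1
        while j < len(subs) and abs(subs[j].merit - subs[i].merit) <= cfg.equal_merit_tol:
            j += 1
        group = subs[i:j]
        group_accs = []
        for s in group:
            a = float(accuracy_fn(s.mask))
            evaluations.append((s, a))
            group_accs.append(a)
            decisions.append(Decision("evaluate",
                                      f"subset {_names(s, d)} merit {s.merit:.6f} "
                                      f"accuracy {a:.6f}"))
        if len(group) > 1:
            merged = reduce(merge_subsets, group)
            merged_acc = float(accuracy_fn(merged.mask))
            evaluations.append((merged, merged_acc))
            best_ind = max(group_accs)
            if merged_acc > best_ind:
                decisions.append(Decision(
                    "case1_merge",
                    f"merged {_names(merged, d)} accuracy {merged_acc:.6f} > best "
                    f"individual {best_ind:.6f}; merged subset kept"))
            else:
                decisions.append(Decision(
                    "case1_individuals",
                    f"merged accuracy {merged_acc:.6f} <= best individual "
                    f"{best_ind:.6f}; individual subsets kept"))
        if j < len(subs) and (subs[i].merit - subs[j].merit) > cfg.drop_threshold:
            decisions.append(Decision(
                "case3_stop",
                f"next merit {subs[j].merit:.6f} falls more than "
                f"{cfg.drop_threshold} below {subs[i].merit:.6f}; walk terminated"))
            break
        i = j

    # ---- select the accuracy-best outcome -------------------------
    order = {id(s): k for k, (s, _) in enumerate(evaluations)}
    selected, best_acc = max(
        evaluations, key=lambda t: (t[1], -t[0].n_features, -order[id(t[0])]))
    tol = cfg.equal_merit_tol
    selected_group = [s for s, a in evaluations
                      if abs(a - best_acc) <= tol and s.origin != "merged"]
    if selected.origin == "merged":
        selected_group = [selected]
    decisions.append(Decision("selected",
                              f"selected {_names(selected, d)} with accuracy {best_acc:.6f}"))

    final_model = None
    report = None
    if evaluator is not None:
        report = evaluator.report(selected.mask)
        final_model = fit_bagged(learner, d, selected.mask, B=cfg.bag_size,
                                 seed=child_seed(cfg.seed, "final"))
    return MergeResult(selected=selected, selected_group=selected_group,
                       evaluations=evaluations, decisions=decisions,
                       final_model=final_model, report=report,
                       ranking=ranking, warning=warning)


def cpemm(d: Dataset, learner: LearnerConfig, pso_cfg: PSOConfig | None = None,
          merge_cfg: MergeConfig | None = None,
          eval_learner: LearnerConfig | None = None) -> MergeResult:
    """Full pipeline: subset search, then merit merging, on preprocessed data.

    ``learner`` drives the wrapper search (the ensemble whose accuracy
    scores subsets); ``eval_learner`` is the Phase III evaluation
    classifier, defaulting to a pruned binary-split decision tree.  All
    searches (including Case 2 re-runs) share one merit cache, and the
    whole run is deterministic given the config seeds.
    """
    if pso_cfg is None:
        pso_cfg = PSOConfig()
    if merge_cfg is None:
        merge_cfg = MergeConfig()
    if eval_learner is None:
        eval_learner = LearnerConfig(kind="c45", seed=child_seed(merge_cfg.seed, "evalkind"))
    evaluator = MeritEvaluator(d, learner, folds=pso_cfg.merit_folds,
                               B=pso_cfg.bag_size, seed=child_seed(pso_cfg.seed, "merit"))
    first_iters = merge_cfg.iteration_schedule[0] if merge_cfg.iteration_schedule else pso_cfg.iterations
    base_cfg = dc_replace(pso_cfg, iterations=first_iters)
    ranking = run_pso(d, base_cfg, learner, evaluator=evaluator)

    def rerun(iterations: int) -> SubsetRanking:
        cfg = dc_replace(pso_cfg, iterations=iterations,
                         seed=child_seed(pso_cfg.seed, "rerun", iterations))
        return run_pso(d, cfg, learner, evaluator=evaluator)

    return merit_merge(ranking, d, eval_learner, merge_cfg, rerun=rerun)
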