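import numpy as np
import pytest

from cpemm.learners import LearnerConfig
from cpemm.meritmerge import MergeConfig, cpemm, merge_subsets, merit_merge
from cpemm.pso import FeatureSubset, PSOConfig, SubsetRanking
from cpemm.synthgen import SyntheticSpec, generate


def fs(bits, merit=None, origin="pso"):
    return FeatureSubset(mask=np.array([c == "1" for c in bits]), merit=merit,
                         origin=origin)


def ranking(*pairs):
    return SubsetRanking(subsets=[fs(b, m) for b, m in pairs])


def stub(table, default=0.5):
    """Accuracy stub: mask bitstring -> accuracy."""
    def f(mask):
        key = "".join("1" if b else "0" for b in mask)
        return table.get(key, default)
    return f


class TestMergeSubsets:
    def test_union(self):
        out = merge_subsets(fs("1100"), fs("0010"))
        assert out.mask_string == "1110"
        assert out.merit is None and out.origin == "merged"

    def test_idempotent(self):
        a = fs("1010")
        assert merge_subsets(a, a).mask_string == "1010"

    def test_commutative(self):
        a, b = fs("1000"), fs("0011")
        assert merge_subsets(a, b).mask_string == merge_subsets(b, a).mask_string

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            merge_subsets(fs("10"), fs("100"))


class TestCaseLogic:
    def test_case1_merge_kept_when_strictly_better(self):
        r = ranking(("1100", 0.90), ("0010", 0.90))
        acc = stub({"1100": 0.90, "0010": 0.90, "1110": 0.95})
        res = merit_merge(r, None, None, MergeConfig(), accuracy_fn=acc)
        assert res.selected.mask_string == "1110"
        assert res.selected.origin == "merged"
        assert any(d.case == "case1_merge" for d in res.decisions)

    def test_case1_individuals_kept_when_merge_does_not_improve(self):
        r = ranking(("1100", 0.90), ("0010", 0.90))
        acc = stub({"1100": 0.90, "0010": 0.89, "1110": 0.88})
        res = merit_merge(r, None, None, MergeConfig(), accuracy_fn=acc)
        assert res.selected.mask_string == "1100"
        assert any(d.case == "case1_individuals" for d in res.decisions)

    def test_case3_terminates_walk_after_merit_drop(self):
        r = ranking(("1000", 0.90), ("0100", 0.60), ("0010", 0.59))
        acc = stub({"1000": 0.91, "0100": 0.99, "0010": 0.99})
        res = merit_merge(r, None, None, MergeConfig(drop_threshold=0.05),
                          accuracy_fn=acc)
        # only the top subset is ever evaluated; the rest are behind the drop
        assert [s.mask_string for s, _ in res.evaluations] == ["1000"]
        assert res.selected.mask_string == "1000"
        assert any(d.case == "case3_stop" for d in res.decisions)

    def test_disabled_drop_threshold_walks_everything(self):
        r = ranking(("1000", 0.90), ("0100", 0.60), ("0010", 0.10))
        acc = stub({"1000": 0.90, "0100": 0.92, "0010": 0.30})
        res = merit_merge(r, None, None, MergeConfig(drop_threshold=1.0),
                          accuracy_fn=acc)
        assert [s.mask_string for s, _ in res.evaluations] == ["1000", "0100", "0010"]
        assert res.selected.mask_string == "0100"

    def test_case2_rerun_escalates_through_schedule(self):
        tied = ranking(("1000", 0.9), ("0100", 0.9), ("0010", 0.9), ("0001", 0.5))
        resolved = ranking(("1000", 0.9), ("0100", 0.7), ("0010", 0.6), ("0001", 0.5))
        calls = []

        def rerun(iters):
            calls.append(iters)
            return resolved

        res = merit_merge(tied, None, None,
                          MergeConfig(iteration_schedule=(60, 80, 100)),
                          rerun=rerun, accuracy_fn=stub({}, default=0.8))
        assert calls == [80]
        assert not res.warning
        assert any(d.case == "case2_rerun" for d in res.decisions)

    def test_case2_exhausted_sets_warning(self):
        tied = ranking(("1000", 0.9), ("0100", 0.9), ("0010", 0.9))
        calls = []

        def rerun(iters):
            calls.append(iters)
            return tied

        res = merit_merge(tied, None, None,
                          MergeConfig(iteration_schedule=(60, 80, 100)),
                          rerun=rerun, accuracy_fn=stub({}, default=0.8))
        assert calls == [80, 100]
        assert res.warning
        assert any(d.case == "case2_exhausted" for d in res.decisions)

    def test_selected_is_accuracy_argmax_of_evaluations(self):
        r = ranking(("1000", 0.9), ("0100", 0.88), ("0011", 0.87))
        acc = stub({"1000": 0.80, "0100": 0.85, "0011": 0.83})
        res = merit_merge(r, None, None, MergeConfig(drop_threshold=1.0),
                          accuracy_fn=acc)
        best = max(a for _, a in res.evaluations)
        sel_acc = dict((s.mask_string, a) for s, a in res.evaluations)[res.selected.mask_string]
        assert sel_acc == best

    def test_empty_ranking_rejected(self):
        with pytest.raises(ValueError):
            merit_merge(SubsetRanking(subsets=[]), None, None, MergeConfig(),
                        accuracy_fn=stub({}))

    def test_decision_log_never_empty(self):
        r = ranking(("10", 0.9))
        res = merit_merge(r, None, None, MergeConfig(), accuracy_fn=stub({}, 0.7))
        assert res.decisions


@pytest.fixture(scope="module")
def small_pipeline_run():
    # moderate effect so every informative feature is individually useful,
    # and no redundant near-copies that could stand in for one
    spec = SyntheticSpec(class_counts=(("NL", 70), ("MCI", 110), ("AD", 60)),
                         n_informative=3, n_redundant=0, n_noise=7,
                         effect=1.8, missing_rate=0.0, seed=17)
    d, gt = generate(spec)
    lc = LearnerConfig(kind="c45", seed=3)
    pso_cfg = PSOConfig(iterations=12, swarm_size=12, top_k=12, seed=5)
    merge_cfg = MergeConfig(iteration_schedule=(12, 18), seed=7)
    return d, gt, cpemm(d, lc, pso_cfg, merge_cfg), lc, pso_cfg, merge_cfg


class TestPipeline:
    def test_selected_covers_planted_features(self, small_pipeline_run):
        d, gt, res, *_ = small_pipeline_run
        missing = gt.informative_mask & ~res.selected.mask
        assert missing.sum() == 0

    def test_selected_excludes_most_noise(self, small_pipeline_run):
        d, gt, res, *_ = small_pipeline_run
        assert (res.selected.mask & gt.noise_mask).sum() <= 2

    def test_selection_covers_signal_groups_under_redundancy(self):
        """With near-copy redundant features, the selected subset covers
        every signal direction through either the informative feature or
        one of its copies (the copies are statistically interchangeable)."""
        spec = SyntheticSpec(class_counts=(("NL", 140), ("MCI", 220), ("AD", 120)),
                             n_informative=3, n_redundant=3, n_noise=4,
                             effect=1.5, missing_rate=0.0, seed=23)
        d, gt = generate(spec)
        res = cpemm(d, LearnerConfig(kind="c45", seed=3),
                    PSOConfig(iterations=12, swarm_size=12, top_k=12, seed=5),
                    MergeConfig(iteration_schedule=(12, 18), seed=7))
        sel = set(np.where(res.selected.mask)[0])
        for j in np.where(gt.informative_mask)[0]:
            group = {j} | {c for c, s in gt.redundant_source.items() if s == j}
            assert sel & group, f"no feature covering signal direction {j}"

    def test_report_accuracy_not_below_top_ranked_subset(self, small_pipeline_run):
        d, gt, res, *_ = small_pipeline_run
        top_acc = dict((s.mask_string, a) for s, a in res.evaluations)[
            res.ranking.subsets[0].mask_string]
        assert res.report.overall_accuracy >= top_acc - 1e-12

    def test_final_model_fits_selected_subset(self, small_pipeline_run):
        d, _, res, *_ = small_pipeline_run
        np.testing.assert_array_equal(res.final_model.subset, res.selected.mask)
        pred = res.final_model.predict(d.X[:, res.selected.mask])
        assert set(pred) <= set(d.classes)

    def test_full_determinism(self, small_pipeline_run):
        d, _, res, lc, pso_cfg, merge_cfg = small_pipeline_run
        res2 = cpemm(d, lc, pso_cfg, merge_cfg)
        assert res2.selected.mask_string == res.selected.mask_string
        assert [str(x) for x in res2.decisions] == [str(x) for x in res.decisions]
        assert res2.report.overall_accuracy == res.report.overall_accuracy
        np.testing.assert_array_equal(res2.report.confusion.counts,
                                      res.report.confusion.counts)

    def test_walk_evaluations_bounded_by_ranking_length(self, small_pipeline_run):
        _, _, res, *_ = small_pipeline_run
        ranked = {s.mask_string for s in res.ranking.subsets}
        non_merged = [s for s, _ in res.evaluations if s.origin != "merged"]
        assert len(non_merged) <= len(ranked)
        assert all(s.mask_string in ranked for s in non_merged)
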