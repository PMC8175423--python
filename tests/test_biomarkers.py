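import numpy as np
import pytest

from voctrait.biomarkers import (
    MLTask,
    ModelResult,
    consensus_biomarkers,
    embedded_rf,
    finalize_model,
    rfe_wrapper,
    run_task,
    stratified_split,
    unique_biomarker_counts,
    upsample_minority,
    zscore_profiles,
)
from voctrait.datamodel import ValidationError
from voctrait.simulate import SimulationScenario, simulate


class TestStratifiedSplit:
    def test_quarter_fraction_gives_three_test_per_class(self):
        y = ["a"] * 12 + ["b"] * 12 + ["c"] * 12 + ["d"] * 12
        train, test = stratified_split(48, y, test_fraction=0.25, seed=0)
        test_labels = [y[i] for i in test]
        assert all(test_labels.count(c) == 3 for c in "abcd")
        assert len(set(train) & set(test)) == 0

    def test_deterministic_under_seed(self):
        y = ["a"] * 8 + ["b"] * 8
        s1 = stratified_split(16, y, seed=7)
        s2 = stratified_split(16, y, seed=7)
        np.testing.assert_array_equal(s1[0], s2[0])
        np.testing.assert_array_equal(s1[1], s2[1])

    def test_singleton_class_named_in_error(self):
        with pytest.raises(ValidationError, match="rare"):
            stratified_split(5, ["a", "a", "a", "a", "rare"])

    def test_train_proportions_within_one_sample(self):
        y = ["a"] * 20 + ["b"] * 10 + ["c"] * 10
        train, _ = stratified_split(40, y, test_fraction=0.25, seed=1)
        train_labels = [y[i] for i in train]
        for cls, total in (("a", 20), ("b", 10), ("c", 10)):
            expected = 0.75 * total
            assert abs(train_labels.count(cls) - expected) <= 1


class TestUpsampleMinority:
    def test_classes_equalized_to_majority(self):
        y = ["big"] * 9 + ["small"] * 3
        idx = upsample_minority(y, seed=0)
        out = [y[i] for i in idx]
        assert out.count("big") == 9 and out.count("small") == 9

    def test_balanced_input_unchanged_sizes(self):
        y = ["a"] * 5 + ["b"] * 5
        idx = upsample_minority(y, seed=0)
        out = [y[i] for i in idx]
        assert out.count("a") == 5 and out.count("b") == 5

    def test_upsampled_rows_are_exact_copies(self):
        y = ["a"] * 6 + ["b"] * 2
        idx = upsample_minority(y, seed=3)
        assert set(idx) <= set(range(8))
        # originals all retained
        assert set(range(8)) <= set(idx)


def _planted_problem(n=120, p=50, informative=5, delta=3.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["pos", "neg"] * (n // 2))
    X = rng.normal(size=(n, p))
    X[y == "pos", :informative] += delta
    names = [f"f{j:02d}" for j in range(p)]
    return X, y, names


class TestRFEWrapper:
    def test_planted_features_ranked_into_top8(self):
        hits = []
        for seed in range(5):
            X, y, names = _planted_problem(seed=seed)
            res = rfe_wrapper(X, y, names, subset_grid=(5, 10, 20), cv_folds=5,
                              seed=seed)
            top8 = set(res.ranked_predictors[:8])
            hits.append(len(top8 & {f"f{j:02d}" for j in range(5)}))
        assert np.median(hits) == 5

    def test_permuted_labels_near_chance_for_all_sizes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 20))
        y = np.array(["a", "b"] * 40)[rng.permutation(80)]
        res = rfe_wrapper(X, y, [f"f{j}" for j in range(20)],
                          subset_grid=(5, 10), cv_folds=5, seed=1)
        assert all(0.3 <= acc <= 0.7 for acc in res.cv_accuracy.values())

    def test_fully_informative_problem_selects_smallest_covering_size(self):
        X, y, names = _planted_problem(n=100, p=12, informative=3, delta=6.0,
                                       seed=2)
        res = rfe_wrapper(X, y, names, subset_grid=(3, 6, 12), cv_folds=5,
                          seed=2)
        assert res.optimal_subset_size == 3

    def test_grid_clamped_to_feature_count(self):
        X, y, names = _planted_problem(n=40, p=8)
        with pytest.warns(UserWarning, match="clamped"):
            res = rfe_wrapper(X, y, names, subset_grid=(5, 50), cv_folds=3,
                              seed=0)
        assert max(res.cv_accuracy) == 8


class TestEmbeddedRF:
    def test_planted_recovery_in_top5(self):
        hits = []
        for seed in range(5):
            X, y, names = _planted_problem(seed=10 + seed)
            res = embedded_rf(X, y, names, cv_folds=5, seed=seed)
            hits.append(len(set(res.ranked_predictors[:5])
                            & {f"f{j:02d}" for j in range(5)}))
        assert np.median(hits) >= 4

    def test_duplicate_columns_still_total_order(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = np.array(["a"] * 30 + ["b"] * 30)
        x[y == "b"] += 2
        X = np.column_stack([x, x, rng.normal(size=60)])
        res = embedded_rf(X, y, ["dup1", "dup2", "noise"], cv_folds=3, seed=0)
        assert sorted(res.ranked_predictors) == ["dup1", "dup2", "noise"]

    def test_deterministic_under_seed(self):
        X, y, names = _planted_problem(n=60, p=10)
        r1 = embedded_rf(X, y, names, cv_folds=3, seed=5)
        r2 = embedded_rf(X, y, names, cv_folds=3, seed=5)
        assert r1.ranked_predictors == r2.ranked_predictors
        assert r1.cv_accuracy == r2.cv_accuracy


class TestFinalizeModel:
    def test_perfect_predictions_binomial_tail(self):
        # class index feature makes the problem trivially separable
        y_tr = np.array(["a"] * 10 + ["b"] * 10)
        X_tr = (y_tr == "b").astype(float)[:, None] * 2 - 1
        y_te = np.array(["a"] * 6 + ["b"] * 6)
        X_te = (y_te == "b").astype(float)[:, None] * 2 - 1
        acc, sens, p = finalize_model(X_tr, y_tr, X_te, y_te, ["f"], ["f"],
                                      seed=0)
        assert acc == 1.0
        assert sens == {"a": 1.0, "b": 1.0}
        assert p == pytest.approx(0.5 ** 12, rel=1e-9)

    def test_uninformative_predictor_p_near_one(self):
        rng = np.random.default_rng(4)
        y_tr = np.array(["a", "b"] * 20)
        y_te = np.array(["a", "b"] * 8)
        acc, _, p = finalize_model(rng.normal(size=(40, 1)), y_tr,
                                   rng.normal(size=(16, 1)), y_te,
                                   ["f"], ["f"], seed=0)
        assert p > 0.05

    def test_class_missing_from_test_gets_null_sensitivity(self):
        y_tr = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        X_tr = np.arange(18.0)[:, None]
        y_te = np.array(["a"] * 3 + ["b"] * 3)
        X_te = np.array([0, 1, 2, 8, 9, 10], dtype=float)[:, None]
        _, sens, _ = finalize_model(X_tr, y_tr, X_te, y_te, ["f"], ["f"], seed=0)
        assert sens["c"] is None

    def test_unknown_predictor_rejected(self):
        with pytest.raises(ValidationError, match="ghost"):
            finalize_model(np.ones((4, 1)), ["a", "a", "b", "b"],
                           np.ones((2, 1)), ["a", "b"], ["ghost"], ["f"])


def _mk_model(model_id, top, acc=0.9, p=0.01, ranked=None):
    ranked = tuple(ranked or top)
    return ModelResult(model_id=model_id, optimal_subset_size=len(top),
                       ranked_predictors=ranked, top15=tuple(top),
                       accuracy=acc, sensitivity={"a": 1.0}, accuracy_p_value=p)


class TestConsensus:
    TASK = MLTask(label="trophic_mode", platform="PTR", seed=0)

    def test_shared_predictors_intersected(self):
        models = [_mk_model("rf_rfe", ["f1", "f2", "f3"]),
                  _mk_model("bagged_rfe", ["f2", "f1", "f4"]),
                  _mk_model("rf_embedded", ["f5", "f1", "f2"])]
        rep = consensus_biomarkers(self.TASK, models)
        assert set(rep.consensus) == {"f1", "f2"}

    def test_mean_rank_arithmetic(self):
        ranked = [["x", "f1"], ["x", "y", "z", "f1"], ["x", "y", "z", "w", "v", "f1"]]
        models = [_mk_model(mid, ["f1", "x", "y", "z", "w", "v"], ranked=r + ["q"])
                  for mid, r in zip(["rf_rfe", "bagged_rfe", "rf_embedded"],
                                    [ranked[0] + ["y", "z", "w", "v"],
                                     ranked[1] + ["w", "v"], ranked[2]])]
        rep = consensus_biomarkers(self.TASK, models)
        assert rep.mean_ranks["f1"] == pytest.approx((2 + 4 + 6) / 3)

    def test_low_accuracy_model_excluded(self):
        models = [_mk_model("rf_rfe", ["f1", "f2"]),
                  _mk_model("bagged_rfe", ["f1", "f3"]),
                  _mk_model("rf_embedded", ["f9"], acc=0.74)]
        rep = consensus_biomarkers(self.TASK, models)
        assert rep.n_passing == 2
        assert set(rep.consensus) == {"f1"}
        assert "2 of 3" in rep.note

    def test_insignificant_model_excluded(self):
        models = [_mk_model("rf_rfe", ["f1"]),
                  _mk_model("bagged_rfe", ["f1"]),
                  _mk_model("rf_embedded", ["f1"], p=0.2)]
        assert consensus_biomarkers(self.TASK, models).n_passing == 2

    def test_no_passing_model_empty_consensus_with_reason(self):
        models = [_mk_model("rf_rfe", ["f1"], acc=0.5)]
        rep = consensus_biomarkers(self.TASK, models)
        assert rep.consensus == () and rep.mean_accuracy is None
        assert rep.note

    def test_aggregated_metrics_are_exact_means(self):
        models = [_mk_model("rf_rfe", ["f1"], acc=0.85, p=0.01),
                  _mk_model("bagged_rfe", ["f1"], acc=0.95, p=0.03)]
        rep = consensus_biomarkers(self.TASK, models)
        assert rep.mean_accuracy == pytest.approx(0.9, abs=1e-12)
        assert rep.mean_p_value == pytest.approx(0.02, abs=1e-12)


@pytest.fixture(scope="module")
def small_task_report():
    sc = SimulationScenario(n_species=16, n_ptr_compounds=25,
                            n_gc_compounds=10, seed=4)
    ptr, _, annotations, _, truth = simulate(sc)
    task = MLTask(label="trophic_mode", platform="PTR", seed=1, cv_folds=4)
    return run_task(ptr, annotations, task, subset_grid=(5, 10)), truth


class TestRunTask:
    def test_report_contains_three_models(self, small_task_report):
        rep, _ = small_task_report
        assert [m.model_id for m in rep.models] == \
            ["rf_rfe", "bagged_rfe", "rf_embedded"]

    def test_consensus_subset_of_every_passing_top15(self, small_task_report):
        rep, _ = small_task_report
        for m in rep.models:
            if m.passed:
                assert set(rep.consensus) <= set(m.top15)

    def test_zscore_profiles_standardized(self, default_study):
        ptr, _, _, _, _ = default_study
        z = zscore_profiles(ptr, ["PTR_000", "PTR_001"])
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_unique_counts_both_conventions(self, small_task_report):
        rep, _ = small_task_report
        counts = unique_biomarker_counts([rep])
        key = "trophic_mode:PTR"
        assert counts["per_task"][key] == len(rep.consensus)
        assert counts["cross_task_deduplicated"][key] == len(rep.consensus)
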