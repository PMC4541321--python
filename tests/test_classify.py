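import numpy as np
import pandas as pd
import pytest

from drwgm.classify import (
    EvalConfig,
    auc,
    c_score,
    cross_dataset_eval,
    fit_extractor,
    fit_logistic,
    greedy_select,
    predict_scores,
    within_dataset_eval,
)
from drwgm.diffstats import LabeledMatrix, ProtocolError

from conftest import build_graphs, labeled


class TestAuc:
    def test_perfect_separation(self):
        assert auc(np.array([1, 2, 3, 4]), np.array([0, 0, 1, 1])) == 1.0

    def test_all_ties_give_half(self):
        assert auc(np.array([1, 1, 1, 1]), np.array([0, 0, 1, 1])) == 0.5

    def test_reversed_orientation_zero(self):
        assert auc(np.array([4, 3, 2, 1]), np.array([0, 0, 1, 1])) == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ProtocolError):
            auc(np.array([1, 2]), np.array([1, 1]))


class TestLogistic:
    def test_separable_feature_gives_auc_one(self):
        feats = pd.DataFrame([[0, 0.1, 0.9, 1.0, 1.1, 0.05]], index=["f1"])
        y = np.array([0, 0, 1, 1, 1, 0])
        clf = fit_logistic(feats, y)
        assert auc(predict_scores(clf, feats), y) == 1.0

    def test_null_feature_near_zero_coefficient(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame([rng.normal(0, 1, 40)], index=["f1"])
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        clf = fit_logistic(feats, y)
        assert abs(clf.coef_[0][0]) < 1.0

    def test_duplicated_samples_leave_decision_unchanged(self):
        # overlapping classes: the likelihood optimum is finite and the tiny
        # ridge is negligible, so duplication cannot move the decision rule
        feats = pd.DataFrame([[0.0, 0.8, 0.4, 1.2, 0.6, 0.2]], index=["f1"])
        y = np.array([0, 0, 1, 1, 1, 0])
        clf1 = fit_logistic(feats, y)
        feats2 = pd.concat([feats, feats], axis=1)
        feats2.columns = range(12)
        clf2 = fit_logistic(feats2, np.r_[y, y])
        assert np.allclose(clf1.coef_, clf2.coef_, atol=1e-3)


def activity_fixture(values: dict[str, list[float]], labels: list[str]) -> LabeledMatrix:
    return labeled(values, labels)


class TestGreedySelect:
    def test_informative_over_noise(self):
        rng = np.random.default_rng(3)
        n = 12
        y = ["A"] * n + ["B"] * n
        info = list(np.r_[rng.normal(0, 0.5, n), rng.normal(3, 0.5, n)])
        noise = list(rng.normal(0, 1, 2 * n))
        ev = activity_fixture({"info": info, "noise": noise}, y)
        rng2 = np.random.default_rng(4)
        info2 = list(np.r_[rng2.normal(0, 0.5, n), rng2.normal(3, 0.5, n)])
        noise2 = list(rng2.normal(0, 1, 2 * n))
        sel = activity_fixture({"info": info2, "noise": noise2}, y)
        assert greedy_select(ev, sel) == ["info"]

    def test_single_feature_always_selected(self):
        ev = activity_fixture({"f1": [0, 0, 1, 1]}, ["A", "A", "B", "B"])
        assert greedy_select(ev, ev) == ["f1"]

    def test_identical_second_feature_rejected(self):
        vals = [0.0, 0.2, 1.1, 1.3, -0.1, 1.2]
        y = ["A", "A", "B", "B", "A", "B"]
        ev = activity_fixture({"f1": vals, "f2": vals}, y)
        assert greedy_select(ev, ev) == ["f1"]


class TestCScore:
    def test_single_top_pathway_product(self):
        rng = np.random.default_rng(0)
        y = ["A"] * 10 + ["B"] * 10
        sep = list(np.r_[rng.normal(0, 1, 10), rng.normal(4, 1, 10)])
        train = activity_fixture({"p1": sep}, y)
        test = activity_fixture({"p1": sep}, y)
        from drwgm.diffstats import gene_ttests

        t = gene_ttests(train)[0].t_score
        res = c_score(train, test, 1)
        assert res.c_score == pytest.approx(t * t)

    def test_identical_cohorts_nonnegative(self):
        rng = np.random.default_rng(1)
        y = ["A"] * 8 + ["B"] * 8
        vals = {f"p{i}": list(rng.normal(0, 1, 16)) for i in range(5)}
        act = activity_fixture(vals, y)
        res = c_score(act, act, 5)
        assert res.c_score >= 0

    def test_label_flip_negates(self):
        rng = np.random.default_rng(2)
        y = ["A"] * 8 + ["B"] * 8
        y_flip = ["B"] * 8 + ["A"] * 8
        vals = {f"p{i}": list(rng.normal(0, 1, 16)) for i in range(4)}
        train = activity_fixture(vals, y)
        test = activity_fixture(vals, y)
        test_flip = activity_fixture(vals, y_flip)
        assert c_score(train, test_flip, 4).c_score == pytest.approx(
            -c_score(train, test, 4).c_score
        )

    def test_n_too_large_rejected(self):
        y = ["A"] * 4 + ["B"] * 4
        act = activity_fixture({"p1": list(range(8))}, y)
        with pytest.raises(ProtocolError):
            c_score(act, act, 2)


class TestProtocols:
    def test_within_auc_count_one_repeat(self, benchmark_sim, benchmark_graph):
        report = within_dataset_eval(
            benchmark_sim.expression,
            benchmark_sim.metabolites,
            benchmark_graph,
            EvalConfig(n_repeats=1, seed=0),
            min_diff_genes=10,
        )
        assert len(report.aucs) == 15
        assert len(report.accuracies) == 15

    def test_within_determinism(self, benchmark_sim, benchmark_graph):
        kwargs = dict(cfg=EvalConfig(n_repeats=1, seed=7), min_diff_genes=10)
        r1 = within_dataset_eval(
            benchmark_sim.expression, benchmark_sim.metabolites, benchmark_graph, **kwargs
        )
        r2 = within_dataset_eval(
            benchmark_sim.expression, benchmark_sim.metabolites, benchmark_graph, **kwargs
        )
        assert r1.aucs == r2.aucs
        assert r1.selected_features == r2.selected_features

    def test_cross_auc_count_one_repeat(self, benchmark_sim, benchmark_graph):
        from drwgm.synthetic import benchmark_spec, simulate

        test_sim = simulate(benchmark_spec(seed=99))
        report = cross_dataset_eval(
            benchmark_sim.expression,
            benchmark_sim.metabolites,
            test_sim.expression,
            benchmark_graph,
            EvalConfig(n_repeats=1, seed=0),
            min_diff_genes=10,
        )
        assert len(report.aucs) == 5

    def test_cross_consistency_with_self(self, benchmark_sim, benchmark_graph):
        report = cross_dataset_eval(
            benchmark_sim.expression,
            benchmark_sim.metabolites,
            benchmark_sim.expression,
            benchmark_graph,
            EvalConfig(n_repeats=1, seed=1),
            min_diff_genes=10,
        )
        # training cohort as its own test set: near-ceiling performance
        assert report.mean_auc > 0.9

    def test_stratification_guard(self, benchmark_graph):
        tiny = labeled(
            {"g": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}, ["A", "A", "A", "A", "A", "B"]
        )
        with pytest.raises(ProtocolError, match="stratified"):
            within_dataset_eval(tiny, None, benchmark_graph, EvalConfig(n_repeats=1))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            EvalConfig(n_folds=1)


class TestExtractor:
    def test_unknown_method(self, benchmark_sim, benchmark_graph):
        with pytest.raises(ValueError):
            fit_extractor(benchmark_sim.expression, benchmark_graph, method="svm")

    def test_mean_extractor_keeps_all_pathways(self, benchmark_sim, benchmark_graph):
        from drwgm.diffstats import z_normalize

        ex = fit_extractor(benchmark_sim.expression, benchmark_graph, method="mean")
        act = ex.train_activities(z_normalize(benchmark_sim.expression))
        assert len(act.feature_ids) == len(benchmark_graph.pathway_index)
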