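import numpy as np
import pandas as pd
import pytest

from drwgm.activity import (
    NotDiscriminativeError,
    PathwayActivityModel,
    activity_test,
    activity_train,
    baseline_activity,
    check_min_diff_genes,
    fit_activity_model,
    pac_activity,
    read_models,
    write_models,
)
from drwgm.diffstats import DiffResult, ProtocolError, z_normalize

from conftest import labeled


def diff(fid, p, t=1.0):
    return DiffResult(feature_id=fid, t_score=t, p_value=p, test="t")


def winf(mapping):
    return pd.Series(mapping)


class TestFitActivityModel:
    def test_p_filter(self):
        model = fit_activity_model(
            "p1",
            {"g1", "g2", "g3"},
            [diff("g1", 0.01), diff("g2", 0.2), diff("g3", 0.04)],
            winf({"g1": 0.3, "g2": 0.2, "g3": 0.1}),
        )
        assert set(model.genes) == {"g1", "g3"}

    def test_none_when_no_gene_passes(self):
        model = fit_activity_model(
            "p1", {"g1"}, [diff("g1", 0.2)], winf({"g1": 0.3})
        )
        assert model is None

    def test_alpha_one_keeps_all(self):
        model = fit_activity_model(
            "p1",
            {"g1", "g2"},
            [diff("g1", 0.5), diff("g2", 0.99)],
            winf({"g1": 0.3, "g2": 0.2}),
            alpha=1.0,
        )
        assert set(model.genes) == {"g1", "g2"}

    def test_genes_ordered_by_weight_then_id(self):
        model = fit_activity_model(
            "p1",
            {"g1", "g2", "g3"},
            [diff(g, 0.01) for g in ("g1", "g2", "g3")],
            winf({"g1": 0.1, "g2": 0.5, "g3": 0.1}),
        )
        assert model.genes == ["g2", "g1", "g3"]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            fit_activity_model(
                "p1", {"g1"}, [diff("g1", 0.01)], winf({"g1": 0.3}), method="svm"
            )


class TestActivityCombination:
    def test_single_gene_reduces_to_z(self):
        z = z_normalize(labeled({"g1": [1.0, 3.0, 2.0, 5.0]}, ["A", "A", "B", "B"]))
        model = PathwayActivityModel("p1", ["g1"], np.array([0.37]), np.array([1.0]))
        a = activity_train(model, z)
        assert np.allclose(a.to_numpy(), z.values.loc["g1"].to_numpy())

    def test_two_gene_hand_computation(self):
        # weights (0.3, 0.4), signs (+, -), both z = 1 -> (0.3-0.4)/0.5 = -0.2
        z = labeled({"g1": [1.0], "g2": [1.0]}, ["A"])
        model = PathwayActivityModel(
            "p1", ["g1", "g2"], np.array([0.3, 0.4]), np.array([1.0, -1.0])
        )
        a = activity_train(model, z)
        assert a.iloc[0] == pytest.approx(-0.2)

    def test_sign_flip_negates_activity(self):
        z = z_normalize(
            labeled({"g1": [1, 2, 3, 7], "g2": [4, 1, 2, 2]}, ["A", "A", "B", "B"])
        )
        m_plus = PathwayActivityModel(
            "p1", ["g1", "g2"], np.array([0.3, 0.2]), np.array([1.0, -1.0])
        )
        m_minus = PathwayActivityModel(
            "p1", ["g1", "g2"], np.array([0.3, 0.2]), np.array([-1.0, 1.0])
        )
        assert np.allclose(
            activity_train(m_plus, z).to_numpy(),
            -activity_train(m_minus, z).to_numpy(),
        )

    def test_weight_scale_invariance(self):
        z = z_normalize(
            labeled({"g1": [1, 2, 3, 7], "g2": [4, 1, 2, 2]}, ["A", "A", "B", "B"])
        )
        m1 = PathwayActivityModel(
            "p1", ["g1", "g2"], np.array([0.3, 0.2]), np.array([1.0, 1.0])
        )
        m2 = PathwayActivityModel(
            "p1", ["g1", "g2"], np.array([3.0, 2.0]), np.array([1.0, 1.0])
        )
        assert np.allclose(
            activity_train(m1, z).to_numpy(), activity_train(m2, z).to_numpy()
        )

    def test_missing_train_gene_raises(self):
        z = z_normalize(labeled({"g1": [1, 2, 3, 4]}, ["A", "A", "B", "B"]))
        model = PathwayActivityModel(
            "p1", ["g1", "gX"], np.array([0.3, 0.4]), np.array([1.0, 1.0])
        )
        with pytest.raises(ProtocolError, match="gX"):
            activity_train(model, z)


class TestActivityTest:
    def test_identical_cohorts_give_identical_activity(self):
        expr = labeled({"g1": [1, 2, 3, 7], "g2": [4, 1, 2, 2]}, ["A", "A", "B", "B"])
        z = z_normalize(expr)
        model = PathwayActivityModel(
            "p1", ["g1", "g2"], np.array([0.5, 0.2]), np.array([1.0, -1.0])
        )
        assert np.allclose(
            activity_train(model, z).to_numpy(),
            activity_test(model, z).to_numpy(),
        )

    def test_absent_gene_dropped_with_renormalization(self):
        z = z_normalize(labeled({"g1": [1, 2, 3, 7]}, ["A", "A", "B", "B"]))
        model = PathwayActivityModel(
            "p1", ["g1", "gX"], np.array([0.3, 0.4]), np.array([1.0, 1.0])
        )
        a = activity_test(model, z)
        # falls back to the single-present-gene case: exactly +z(g1)
        assert np.allclose(a.to_numpy(), z.values.loc["g1"].to_numpy())

    def test_all_genes_absent_raises(self):
        z = z_normalize(labeled({"gY": [1, 2, 3, 4]}, ["A", "A", "B", "B"]))
        model = PathwayActivityModel("p1", ["gX"], np.array([0.3]), np.array([1.0]))
        with pytest.raises(ProtocolError):
            activity_test(model, z)


class TestBaselines:
    def test_mean_and_median_two_genes(self):
        z = labeled({"g1": [1.0], "g2": [3.0]}, ["A"])
        a_mean = baseline_activity("p1", {"g1", "g2"}, z, "mean")
        a_median = baseline_activity("p1", {"g1", "g2"}, z, "median")
        assert a_mean.iloc[0] == pytest.approx(2.0)
        assert a_median.iloc[0] == pytest.approx(2.0)

    def test_median_robust_to_outlier(self):
        z = labeled({"g1": [1.0], "g2": [2.0], "g3": [9.0]}, ["A"])
        a = baseline_activity("p1", {"g1", "g2", "g3"}, z, "median")
        assert a.iloc[0] == pytest.approx(2.0)

    def test_single_member(self):
        z = labeled({"g1": [1.5, -0.5]}, ["A", "B"])
        a_mean = baseline_activity("p1", {"g1"}, z, "mean")
        a_median = baseline_activity("p1", {"g1"}, z, "median")
        assert np.allclose(a_mean.to_numpy(), [1.5, -0.5])
        assert np.allclose(a_mean.to_numpy(), a_median.to_numpy())

    def test_no_measured_members_dropped(self):
        z = labeled({"g1": [1.0]}, ["A"])
        assert baseline_activity("p1", {"gX"}, z, "mean") is None

    def test_uses_all_members_without_p_filter(self):
        z = labeled({"g1": [1.0], "g2": [5.0]}, ["A"])
        a = baseline_activity("p1", {"g1", "g2"}, z, "mean")
        assert a.iloc[0] == pytest.approx(3.0)


class TestPacActivity:
    def test_single_member(self):
        z = z_normalize(labeled({"g1": [1, 2, 5, 6]}, ["A", "A", "B", "B"]))
        model = pac_activity("p1", {"g1"}, [diff("g1", 0.01, t=3.0)], z)
        assert model.genes == ["g1"]
        assert model.method == "pac"

    def test_redundant_discriminative_genes_both_enter(self):
        # two correlated informative genes: averaging cancels noise, |t| rises
        rng = np.random.default_rng(1)
        n = 10
        signal = np.r_[np.zeros(n), np.ones(n) * 2]
        g1 = signal + rng.normal(0, 1.0, 2 * n)
        g2 = signal + rng.normal(0, 1.0, 2 * n)
        expr = labeled({"g1": list(g1), "g2": list(g2)}, ["A"] * n + ["B"] * n)
        z = z_normalize(expr)
        from drwgm.diffstats import gene_ttests

        gd = gene_ttests(z)
        model = pac_activity("p1", {"g1", "g2"}, gd, z)
        assert set(model.genes) == {"g1", "g2"}

    def test_noise_gene_rejected(self):
        rng = np.random.default_rng(2)
        n = 10
        signal = np.r_[np.zeros(n), np.ones(n) * 3]
        g1 = signal + rng.normal(0, 0.5, 2 * n)
        g2 = rng.normal(0, 1.0, 2 * n)  # pure noise
        expr = labeled({"g1": list(g1), "g2": list(g2)}, ["A"] * n + ["B"] * n)
        z = z_normalize(expr)
        from drwgm.diffstats import gene_ttests

        gd = gene_ttests(z)
        model = pac_activity("p1", {"g1", "g2"}, gd, z)
        assert model.genes == ["g1"]


class TestMinDiffGenesGuard:
    def test_guard_triggers(self):
        results = [diff(f"g{i}", 0.5) for i in range(100)]
        with pytest.raises(NotDiscriminativeError, match="50"):
            check_min_diff_genes(results)

    def test_guard_passes(self):
        results = [diff(f"g{i}", 0.01) for i in range(60)]
        assert check_min_diff_genes(results) == 60


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path):
        model = PathwayActivityModel(
            "p1", ["g1", "g2"], np.array([0.3, 0.2]), np.array([1.0, -1.0])
        )
        path = tmp_path / "models.json"
        write_models([model], path)
        (back,) = read_models(path)
        assert back.pathway_id == model.pathway_id
        assert back.genes == model.genes
        assert np.allclose(back.weights, model.weights)
        assert np.allclose(back.signs, model.signs)
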