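import numpy as np
import pandas as pd
import pytest

from brainmix import structure
from brainmix.models import FittedModel, ModelSpec, fit_model

from conftest import toy_dataset


class _LinearWeights:
    """Minimal estimator: prediction = X @ w (for controlled importance tests)."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.w


def _manual_model(columns, weights):
    return FittedModel(
        spec=ModelSpec("linear"), estimator=_LinearWeights(weights),
        columns=list(columns),
    )


class TestCrossVersionCorrelations:
    def test_identical_versions_give_r_one(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((30, 3))
        ds = toy_dataset({"v5": vals, "v7": vals.copy()})
        out = structure.cross_version_correlations(ds)
        overall = out[out["age_bin"] == "overall"]
        np.testing.assert_allclose(overall["r"], 1.0, atol=1e-12)

    def test_negated_versions_give_r_minus_one(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((30, 3))
        ds = toy_dataset({"v5": vals, "v7": -vals})
        out = structure.cross_version_correlations(ds)
        np.testing.assert_allclose(out[out["age_bin"] == "overall"]["r"], -1.0, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((40, 3))
        ds = toy_dataset({"v5": vals, "v7": 3.0 * vals + 7.0})
        out = structure.cross_version_correlations(ds)
        np.testing.assert_allclose(out[out["age_bin"] == "overall"]["r"], 1.0, atol=1e-10)

    def test_decade_bins_partition_and_flag_small_bins(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((20, 3))
        ds = toy_dataset({"v5": vals, "v7": vals}, ages=np.linspace(55, 80, 20))
        out = structure.cross_version_correlations(ds, age_bins=(49.0, 50.0, 83.0))
        first = out[out["age_bin"] == "[49,50)"]
        assert (first["n"] == 0).all()
        assert first["insufficient_n"].all()
        assert first["r"].isna().all()
        last = out[out["age_bin"] == "[50,83]"]
        assert (last["n"] == 20).all()
        np.testing.assert_allclose(last["r"], 1.0, atol=1e-12)

    def test_last_bin_absorbs_upper_edge(self):
        vals = np.random.default_rng(4).standard_normal((10, 3))
        ds = toy_dataset({"v5": vals, "v7": vals}, ages=np.full(10, 83.0))
        out = structure.cross_version_correlations(
            ds, age_bins=structure.DEFAULT_AGE_BINS
        )
        assert (out[out["age_bin"] == "[70,83]"]["n"] == 10).all()

    def test_invalid_bins(self):
        ds = toy_dataset({"v5": np.eye(5, 3), "v7": np.eye(5, 3)})
        with pytest.raises(ValueError, match="strictly increasing"):
            structure.cross_version_correlations(ds, age_bins=(60.0, 50.0))


class TestAgeCorrelations:
    def test_feature_equal_to_age_has_r_one(self):
        n = 25
        ages = np.linspace(50, 80, n)
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((n, 3))
        vals[:, 0] = ages
        ds = toy_dataset({"v5": vals, "v7": vals}, ages=ages)
        out = structure.age_correlations(ds, "v5")
        assert out.loc[0, "r"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_flagged(self):
        vals = np.random.default_rng(6).standard_normal((20, 3))
        vals[:, 1] = 1.0  # exactly constant, so the column SD is exactly zero
        ds = toy_dataset({"v5": vals, "v7": vals})
        out = structure.age_correlations(ds, "v5")
        assert out.loc[1, "zero_variance"]
        assert np.isnan(out.loc[1, "r"])
        assert not out.loc[0, "zero_variance"]

    def test_id_subset_and_unknown_version(self):
        vals = np.random.default_rng(7).standard_normal((20, 3))
        ds = toy_dataset({"v5": vals, "v7": vals})
        sub = structure.age_correlations(ds, "v5", ids=ds.participant_ids[:10])
        assert len(sub) == 3
        with pytest.raises(KeyError, match="unknown version"):
            structure.age_correlations(ds, "v6")
        with pytest.raises(ValueError, match="at least 3"):
            structure.age_correlations(ds, "v5", ids=ds.participant_ids[:2])


class TestPermutationImportance:
    def test_ignored_features_get_zero_importance_and_lexicographic_ties(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=["c", "a", "b"])
        y = X["c"].to_numpy() * 2.0
        model = _manual_model(X.columns, [2.0, 0.0, 0.0])
        ranking = structure.permutation_importance(model, X, y, n_repeats=3, seed=0)
        by_name = {name: (imp, rank) for name, imp, rank in ranking.entries}
        assert by_name["a"][0] == 0.0 and by_name["b"][0] == 0.0
        assert by_name["c"][1] == 1
        assert by_name["a"][1] == 2  # exact ties broken by feature name
        assert by_name["b"][1] == 3

    def test_recovers_planted_importance_order(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=["x0", "x1", "x2"])
        y = 3.0 * X["x0"] + 0.5 * X["x1"] + 0.05 * rng.standard_normal(200)
        model = fit_model(ModelSpec("linear"), X, y)
        ranking = structure.permutation_importance(model, X, y, n_repeats=5, seed=1)
        assert ranking.top(3) == ["x0", "x1", "x2"]
        frame = ranking.to_frame()
        assert list(frame["rank"]) == [1, 2, 3]
        assert frame["importance"].is_monotonic_decreasing

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.standard_normal((60, 3)), columns=["x0", "x1", "x2"])
        y = X.sum(axis=1).to_numpy()
        model = fit_model(ModelSpec("linear"), X, y)
        a = structure.permutation_importance(model, X, y, n_repeats=4, seed=3)
        b = structure.permutation_importance(model, X, y, n_repeats=4, seed=3)
        assert a.entries == b.entries

    def test_rank_validation(self):
        with pytest.raises(ValueError, match="permutation"):
            structure.ImportanceRanking(entries=[("a", 1.0, 1), ("b", 0.5, 3)], n_repeats=1)

    def test_cross_version_top10_overlap(self, default_cohort):
        """Both versions' models must agree on most of the top-10 features."""
        dataset, _ = default_cohort
        age = dataset.demographics["age"]
        rankings = {}
        for v in ("v5", "v7"):
            X = dataset.features_by_version[v].copy()
            X.index = range(len(X))
            model = fit_model(ModelSpec("linear"), X, age.to_numpy())
            rankings[v] = structure.permutation_importance(
                model, X, age.to_numpy(), n_repeats=5, seed=2
            )
        overlap = set(rankings["v5"].top(10)) & set(rankings["v7"].top(10))
        assert len(overlap) >= 7


class TestPCA:
    def test_correlated_pair_dominates_first_component(self):
        rng = np.random.default_rng(11)
        n = 2000
        shared = rng.standard_normal(n)
        vals = np.column_stack([
            shared,                       # thickness
            rng.standard_normal(n),       # area (independent)
            shared + 1e-6 * rng.standard_normal(n),  # volume (≈ thickness)
        ])
        ds = toy_dataset({"v5": vals, "v7": vals})
        out = structure.pca_by_feature_type(ds, n_components=3)
        for v in ("v5", "v7"):
            s = out[v]
            assert s.variance_explained[0] == pytest.approx(2.0 / 3.0, abs=0.01)
            comp = s.composition.iloc[0]
            assert comp["thickness"] == pytest.approx(0.5, abs=0.02)
            assert comp["volume"] == pytest.approx(0.5, abs=0.02)
            assert comp["area"] == pytest.approx(0.0, abs=0.02)
            np.testing.assert_allclose(s.composition.sum(axis=1), 1.0, atol=1e-8)

    def test_component_cap_and_degenerate_features(self):
        rng = np.random.default_rng(12)
        vals = rng.standard_normal((5, 3))
        ds = toy_dataset({"v5": vals, "v7": vals})
        out = structure.pca_by_feature_type(ds, n_components=10)
        assert len(out["v5"].variance_explained) == 3  # min(10, p=3, n-1=4)
        vals2 = vals.copy()
        vals2[:, 2] = 0.0
        ds2 = toy_dataset({"v5": vals2, "v7": vals2})
        with pytest.raises(ValueError, match="zero-variance"):
            structure.pca_by_feature_type(ds2)

    def test_summary_validation(self):
        comp = pd.DataFrame({"thickness": [0.5], "area": [0.5]})
        with pytest.raises(ValueError, match="non-increasing"):
            structure.PCASummary("v5", np.array([0.2, 0.5]),
                                 pd.concat([comp, comp], ignore_index=True))
        with pytest.raises(ValueError, match="sum to 1"):
            structure.PCASummary("v5", np.array([0.9]),
                                 pd.DataFrame({"thickness": [0.4], "area": [0.4]}))


class TestImportanceByMeasure:
    def test_rows_and_counts(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.standard_normal((40, 3)))
        ds = toy_dataset({"v5": X.to_numpy(), "v7": X.to_numpy()})
        X.columns = ds.feature_columns
        y = ds.demographics["age"].to_numpy()
        model = fit_model(ModelSpec("linear"), X, y)
        ranking = structure.permutation_importance(model, X, y, n_repeats=2, seed=0)
        out = structure.importance_by_measure(ranking, ds)
        assert set(out["measure"]) == {"thickness", "area", "volume"}
        assert (out["n_features"] == 1).all()
        # single-member indicators still yield finite correlations here
        assert out["r"].notna().all()


class TestWriters:
    def test_tables_written(self, tmp_path):
        rng = np.random.default_rng(14)
        vals = rng.standard_normal((30, 3))
        ds = toy_dataset({"v5": vals, "v7": vals + 0.1 * rng.standard_normal((30, 3))})
        correlations = structure.cross_version_correlations(ds)
        age_corrs = {v: structure.age_correlations(ds, v) for v in ("v5", "v7")}
        pca = structure.pca_by_feature_type(ds)
        written = structure.write_structure_tables(
            tmp_path, correlations=correlations, age_corrs=age_corrs, pca=pca
        )
        names = {p.name for p in written}
        assert names == {"cross_version_correlations.csv", "age_correlations.csv",
                         "pca_summary.csv"}
        stacked = pd.read_csv(tmp_path / "age_correlations.csv")
        assert set(stacked["version"]) == {"v5", "v7"}
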