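import numpy as np
import pandas as pd
import pytest

from brainmix import stats as bstats


class TestComputeMetrics:
    def test_toy_oracle(self):
        y = np.array([10.0, 20.0, 30.0, 40.0])
        yhat = np.array([8.0, 22.0, 26.0, 44.0])  # residuals 2, -2, 4, -4
        s = bstats.compute_metrics(y, yhat, k=204)
        assert s.MAE == pytest.approx(3.0, abs=1e-12)
        assert s.RMSE == pytest.approx(np.sqrt(10.0), abs=1e-12)
        assert s.R == pytest.approx(np.corrcoef(y, yhat)[0, 1], abs=1e-12)
        assert s.n == 4 and s.k == 204

    @pytest.mark.parametrize("k,n", [(204, 500), (48, 150), (3, 10)])
    def test_bic_minus_aic_identity(self, k, n):
        rng = np.random.default_rng(k + n)
        y = rng.normal(60, 7, n)
        yhat = y + rng.normal(0, 3, n)
        s = bstats.compute_metrics(y, yhat, k=k)
        assert s.BIC - s.AIC == pytest.approx(k * (np.log(n) - 2.0), rel=1e-12)

    def test_adjusted_r2_with_covariates(self):
        rng = np.random.default_rng(0)
        n = 200
        y = rng.normal(60, 7, n)
        yhat = y + rng.normal(0, 4, n)
        cov = pd.DataFrame({"sex": rng.choice(["F", "M"], n),
                            "site": rng.choice([1, 2, 3], n)})
        s = bstats.compute_metrics(y, yhat, covariates=cov, k=10)
        assert s.R2_adj_corrected is not None
        assert -0.1 < s.R2_adj_corrected < 1.0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="length"):
            bstats.compute_metrics([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="at least 3"):
            bstats.compute_metrics([1, 2], [1, 2])
        with pytest.raises(ValueError, match="constant"):
            bstats.compute_metrics([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestDependentCorrelations:
    def test_zou_interval_contains_point_difference(self):
        lo, hi = bstats.zou_interval(0.6, 0.4, 0.5, n=100)
        assert lo < 0.2 < hi

    def test_zou_interval_antisymmetric(self):
        lo, hi = bstats.zou_interval(0.6, 0.4, 0.5, n=100)
        lo2, hi2 = bstats.zou_interval(0.4, 0.6, 0.5, n=100)
        assert lo == pytest.approx(-hi2, abs=1e-12)
        assert hi == pytest.approx(-lo2, abs=1e-12)

    def test_zou_interval_narrows_with_n(self):
        w = [hi - lo for lo, hi in
             (bstats.zou_interval(0.5, 0.3, 0.4, n=n) for n in (50, 500, 5000))]
        assert w[0] > w[1] > w[2]

    def test_hittner_zero_under_equality(self):
        Z, p = bstats.hittner_test(0.5, 0.5, 0.4, n=200)
        assert Z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_hittner_sign_and_monotonicity(self):
        Z1, p1 = bstats.hittner_test(0.6, 0.4, 0.5, n=100)
        Z2, p2 = bstats.hittner_test(0.6, 0.4, 0.5, n=400)
        assert Z1 > 0 and Z2 > Z1 and p2 < p1
        Zneg, _ = bstats.hittner_test(0.4, 0.6, 0.5, n=100)
        assert Zneg == pytest.approx(-Z1, abs=1e-12)

    def test_invalid_triples_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            bstats.zou_interval(0.5, 0.3, 0.4, n=3)
        with pytest.raises(ValueError, match="strictly inside"):
            bstats.hittner_test(1.0, 0.3, 0.4, n=50)
        with pytest.raises(ValueError, match="positive semi-definite"):
            bstats.zou_interval(0.9, -0.9, 0.9, n=50)

    def test_corr_comparison_wires_sample_correlations(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=300)
        a = y + rng.normal(size=300)
        b = 0.3 * y + rng.normal(size=300)
        cmp_ = bstats.corr_comparison(y, a, b)
        assert cmp_.r_jk == pytest.approx(np.corrcoef(y, a)[0, 1])
        assert cmp_.r_jh == pytest.approx(np.corrcoef(y, b)[0, 1])
        assert cmp_.r_kh == pytest.approx(np.corrcoef(a, b)[0, 1])
        assert cmp_.r_diff == pytest.approx(cmp_.r_jk - cmp_.r_jh)
        assert cmp_.CI_lower < cmp_.r_diff < cmp_.CI_upper


class TestFDR:
    def test_handworked_example(self):
        adjusted = bstats.fdr_adjust([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(adjusted, [0.02, 0.02, 0.04, 0.04], atol=1e-12)

    def test_order_preserved_and_bounded(self):
        p = [0.9, 0.001, 0.5, 0.02]
        adj = bstats.fdr_adjust(p)
        assert len(adj) == 4
        assert np.all(adj <= 1.0) and np.all(adj >= p)
        assert adj[1] == adj.min()

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bstats.fdr_adjust([0.5, 1.2])


def _two_cell_records(seed=0, n=40, shift=1.5):
    rng = np.random.default_rng(seed)
    ids = np.arange(1, n + 1)
    age = rng.uniform(50, 80, n)
    sex = rng.choice(["F", "M"], n)
    site = rng.choice([1, 2, 3], n)
    rows = []
    for cell, delta, src in (("a->x", 0.0, "a"), ("b->x", shift, "b")):
        pred = age + delta + rng.normal(0, 1.0, n)
        for j in range(n):
            rows.append({"cell": cell, "participant_id": ids[j],
                         "predicted_age": pred[j], "age": age[j],
                         "sex": sex[j], "site": site[j],
                         "train_source": src})
    return pd.DataFrame(rows)


class TestMarginalContrasts:
    def test_matches_normal_equations_oracle(self):
        records = _two_cell_records(seed=3)
        [res] = bstats.marginal_contrasts(records)
        # oracle: OLS of predicted age on intercept, cell-b indicator, age,
        # female indicator, and site dummies, solved by normal equations
        f = records
        design = np.column_stack([
            np.ones(len(f)),
            (f["cell"] == "b->x").to_numpy(float),
            f["age"].to_numpy(),
            (f["sex"] == "F").to_numpy(float),
            (f["site"] == 2).to_numpy(float),
            (f["site"] == 3).to_numpy(float),
        ])
        beta = np.linalg.solve(design.T @ design,
                               design.T @ f["predicted_age"].to_numpy())
        assert res.label == "a->x & b->x"
        assert res.estimate == pytest.approx(-beta[1], abs=1e-8)

    def test_recovers_planted_shift(self):
        records = _two_cell_records(seed=4, n=200, shift=2.0)
        [res] = bstats.marginal_contrasts(records)
        assert res.estimate == pytest.approx(-2.0, abs=0.5)
        assert res.p < 1e-6 and res.p_FDR == pytest.approx(res.p)

    def test_requires_common_participants(self):
        records = _two_cell_records(seed=5)
        records = records.drop(records[records["cell"] == "a->x"].index[:3])
        with pytest.raises(ValueError, match="same participants"):
            bstats.marginal_contrasts(records)

    def test_requires_two_cells(self):
        records = _two_cell_records(seed=6)
        with pytest.raises(ValueError, match="two cells"):
            bstats.marginal_contrasts(records[records["cell"] == "a->x"])


class TestSexDifference:
    def test_sign_convention_female_positive(self):
        rng = np.random.default_rng(7)
        n = 300
        age = rng.uniform(50, 80, n)
        sex = rng.choice(["F", "M"], n)
        records = pd.DataFrame({
            "cell": "mix->mix", "participant_id": np.arange(n),
            "predicted_age": age + 2.0 * (sex == "F") + rng.normal(0, 1, n),
            "age": age, "sex": sex, "site": rng.choice([1, 2, 3], n),
        })
        [res] = bstats.sex_difference(records)
        assert res.estimate == pytest.approx(2.0, abs=0.4)
        assert res.p < 1e-6

    def test_single_sex_cell_rejected(self):
        records = _two_cell_records(seed=8)
        records["sex"] = "F"
        with pytest.raises(ValueError, match="single sex"):
            bstats.sex_difference(records)


class TestSiteModel:
    def test_two_group_fit_reports_wald(self):
        records = _two_cell_records(seed=9, n=120)
        res = bstats.site_mixed_model(records)
        assert set(res.site_coefficients) == {"C(site)[T.2]", "C(site)[T.3]"}
        assert res.wald_df == 2
        assert 0.0 <= res.p <= 1.0
        assert res.group_variance >= 0.0

    def test_single_group_falls_back_to_ols(self):
        records = _two_cell_records(seed=10)
        records["train_source"] = "mix"
        res = bstats.site_mixed_model(records)
        assert res.boundary is True
        assert res.group_variance == 0.0

    def test_needs_multiple_sites(self):
        records = _two_cell_records(seed=11)
        records["site"] = 1
        with pytest.raises(ValueError, match="two sites"):
            bstats.site_mixed_model(records)


class TestPairedCorrelationTest:
    def test_matches_scipy_and_effect_size(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(-0.3, 0.0, 50)
        b = a + rng.normal(0.02, 0.01, 50)
        res = bstats.paired_correlation_test(a, b)
        from scipy import stats as sps

        t, p = sps.ttest_rel(a, b)
        assert res.t == pytest.approx(float(t))
        assert res.p == pytest.approx(float(p))
        diff = a - b
        assert res.d == pytest.approx(float(diff.mean() / diff.std(ddof=1)))
        assert res.n == 50

    def test_validation(self):
        with pytest.raises(ValueError, match="at least 3"):
            bstats.paired_correlation_test([0.1, 0.2], [0.1, 0.3])
        with pytest.raises(ValueError, match="zero-variance"):
            bstats.paired_correlation_test([0.0, 0.25, 0.5], [0.25, 0.5, 0.75])
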