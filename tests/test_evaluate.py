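"""Evaluation metrics against independent oracles and constructions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylancestry.evaluate import (
    association_test,
    centroid_metrics,
    covariate_ancestry_assoc,
    ewas_lm,
    genomic_inflation,
    mvalues,
    partial_r2,
    pc_correlations,
    silhouette,
)


def brute_force_silhouette(points, labels):
    """Library-free double-loop silhouette; singleton clusters get 0."""
    n = len(points)
    dist = np.array(
        [[np.sqrt(((points[i] - points[j]) ** 2).sum()) for j in range(n)] for i in range(n)]
    )
    out = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([dist[i, j] for j in own])
        b = min(
            np.mean([dist[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels) - {labels[i]}
        )
        out[i] = (b - a) / max(a, b)
    return out


class TestSilhouette:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = rng.integers(6, 16)
            pts = rng.normal(size=(n, 3))
            labels = rng.integers(0, 3, n)
            while len(np.unique(labels)) < 2:
                labels = rng.integers(0, 3, n)
            s, mean_s, _ = silhouette(pts, labels)
            expected = brute_force_silhouette(pts, labels)
            np.testing.assert_allclose(s, expected, atol=1e-12)
            assert mean_s == pytest.approx(expected.mean(), abs=1e-12)

    def test_well_separated_clusters_score_high(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.05, (50, 3)), rng.normal(5, 0.05, (50, 3))])
        _, mean_s, _ = silhouette(pts, np.repeat([0, 1], 50))
        assert mean_s > 0.9

    def test_interleaved_clouds_score_near_zero(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, (200, 3))
        _, mean_s, _ = silhouette(pts, rng.integers(0, 2, 200))
        assert abs(mean_s) < 0.1

    def test_single_label_rejected(self):
        with pytest.raises(ValueError, match="2 labels"):
            silhouette(np.zeros((4, 3)), np.zeros(4))


class TestCentroidMetrics:
    def test_within_distance_arithmetic(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        within, _ = centroid_metrics(pts, ["a", "a"])
        assert within["a"] == pytest.approx(1.0)

    def test_between_distance_345_triangle(self):
        pts = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        _, between = centroid_metrics(pts, ["a", "b"])
        assert between.loc["a", "b"] == pytest.approx(5.0)

    def test_singleton_cluster_within_zero(self):
        within, _ = centroid_metrics(np.array([[1.0, 1, 1]]), ["solo"])
        assert within["solo"] == 0.0

    def test_between_matrix_is_a_metric(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(30, 3))
        labels = rng.integers(0, 4, 30)
        _, between = centroid_metrics(pts, labels)
        b = between.to_numpy()
        np.testing.assert_allclose(b, b.T, atol=1e-12)
        assert np.allclose(np.diag(b), 0)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert b[i, j] <= b[i, k] + b[k, j] + 1e-12


class TestAssociationTest:
    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(4)
        rejections = 0
        n_sims = 200
        groups = np.repeat([0, 1, 2], 20)
        for _ in range(n_sims):
            y = rng.normal(size=60)
            rejections += association_test(y, groups)["p"] < 0.05
        assert 0.02 <= rejections / n_sims <= 0.10

    def test_large_shift_detected(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)])
        res = association_test(y, np.repeat([0, 1], 30))
        assert res["p"] < 1e-6

    def test_skewed_data_selects_kruskal(self):
        rng = np.random.default_rng(6)
        y = np.concatenate([rng.lognormal(0, 2.0, 40), rng.lognormal(0.2, 2.0, 40)])
        res = association_test(y, np.repeat([0, 1], 40))
        assert res["test_name"] == "kruskal"

    def test_tiny_group_falls_back_to_kruskal(self):
        y = np.array([1.0, 2, 3, 4, 5, 9.0])
        res = association_test(y, np.array([0, 0, 0, 0, 1, 1]))
        assert res["test_name"] == "kruskal"


class TestPcCorrelations:
    def test_identical_pcs_give_identity_pattern(self):
        rng = np.random.default_rng(7)
        raw = rng.normal(size=(100, 3))
        x = np.linalg.qr(raw - raw.mean(axis=0))[0]  # centered orthonormal columns
        mat, _ = pc_correlations(x, x)
        np.testing.assert_allclose(np.diag(mat.to_numpy()), 1.0, atol=1e-12)
        off = mat.to_numpy() - np.diag(np.diag(mat.to_numpy()))
        assert np.abs(off).max() < 1e-8

    def test_sign_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(50, 3))
        mat, _ = pc_correlations(x, -x)
        assert mat.iloc[0, 0] == pytest.approx(1.0)

    def test_independent_vectors_uncorrelated(self):
        rng = np.random.default_rng(9)
        mat, mean = pc_correlations(rng.normal(size=(1000, 3)), rng.normal(size=(1000, 3)))
        assert (mat.to_numpy() < 0.1).all()
        assert mean < 0.1

    def test_constant_vector_reported_missing(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(20, 3))
        g = rng.normal(size=(20, 3))
        a[:, 2] = 1.0
        mat, mean = pc_correlations(a, g)
        assert mat.iloc[2].isna().all()
        assert np.isfinite(mean)


class TestPartialR2:
    def test_matches_independent_sse_computation(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        xa = rng.normal(size=(30, 2))
        xb = rng.normal(size=(30, 2))
        y = xa @ [1.0, -0.5] + xb @ [0.3, 0.2] + rng.normal(0, 0.5, 30)

        def sse(x):
            exog = sm.add_constant(x) if x is not None else np.ones((30, 1))
            return float(sm.OLS(y, exog).fit().ssr)

        got = partial_r2(y, xa, xb)
        sse_ab = sse(np.column_stack([xa, xb]))
        assert got["r2_A_unique"] == pytest.approx((sse(xb) - sse_ab) / sse(xb), abs=1e-10)
        assert got["r2_B_unique"] == pytest.approx((sse(xa) - sse_ab) / sse(xa), abs=1e-10)
        assert got["r2_joint"] == pytest.approx(1 - sse_ab / sse(None), abs=1e-10)

    def test_limiting_case_y_linear_in_a(self):
        rng = np.random.default_rng(12)
        xa = rng.normal(size=(40, 2))
        xb = rng.normal(size=(40, 2))
        y = xa @ [2.0, 1.0]
        got = partial_r2(y, xa, xb)
        assert got["r2_A_unique"] > 0.999
        assert got["r2_B_unique"] < 0.01

    def test_shared_columns_have_no_unique_variance(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(40, 1))
        y = (x[:, 0] + rng.normal(0, 0.1, 40))
        noise_a = x + rng.normal(0, 1e-6, x.shape)
        noise_b = x + rng.normal(0, 1e-6, x.shape)
        got = partial_r2(y, noise_a, noise_b)
        assert got["r2_A_unique"] < 0.05 and got["r2_B_unique"] < 0.05
        assert got["r2_joint"] > 0.9

    def test_joint_bounds(self):
        rng = np.random.default_rng(14)
        got = partial_r2(rng.normal(size=50), rng.normal(size=(50, 2)), rng.normal(size=(50, 2)))
        assert got["r2_joint"] <= 1.0
        assert got["r2_joint"] >= max(got["r2_A_unique"], got["r2_B_unique"]) - 1e-9


class TestGenomicInflation:
    def test_uniform_null_lambda_near_one(self):
        rng = np.random.default_rng(15)
        lam = genomic_inflation(rng.uniform(0, 1, 100000) + 1e-12)
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_halved_pvalues_inflate(self):
        p = np.linspace(1e-6, 1, 10000)
        assert genomic_inflation(p / 2) > 1.0

    def test_scaled_chi_square_construction(self):
        rng = np.random.default_rng(16)
        chi = 1.2 * rng.chisquare(1, 200000)
        lam = genomic_inflation(stats.chi2.sf(chi, 1) + 1e-300)
        assert lam == pytest.approx(1.2, abs=0.03)

    def test_permutation_invariant_and_monotone(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(0.01, 1, 5000)
        lam = genomic_inflation(p)
        assert genomic_inflation(rng.permutation(p)) == pytest.approx(lam, abs=1e-12)
        assert genomic_inflation(p * 0.8) >= lam

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.concatenate([np.zeros(1), np.full(200, 0.5)]))
        with pytest.raises(ValueError, match="100"):
            genomic_inflation(np.full(50, 0.5))


class TestEwas:
    def test_null_lambda_calibrated(self):
        rng = np.random.default_rng(18)
        n, probes = 80, 4000
        m = rng.normal(0, 1, (probes, n))
        pheno = rng.integers(0, 2, n).astype(float)
        cov = rng.normal(size=(n, 3))
        lam = genomic_inflation(ewas_lm(m, pheno, cov))
        assert 0.9 <= lam <= 1.1

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(19)
        n = 60
        pheno = np.repeat([0.0, 1.0], n // 2)
        m = rng.normal(0, 1, (200, n))
        m[7] += 5.0 * pheno  # 5 sigma shift on one probe
        p = ewas_lm(m, pheno, None)
        assert p[7] < 1e-6

    def test_mvalue_transform_clips(self):
        m = mvalues(np.array([0.0, 0.5, 1.0]))
        assert np.isfinite(m).all()
        assert m[1] == pytest.approx(0.0)


class TestCovariateAncestryAssociation:
    def test_group_shift_detected(self):
        rng = np.random.default_rng(20)
        groups = np.repeat(["EUR", "AFR"], 30)
        factors = pd.DataFrame({
            "ctrlPC1": np.where(groups == "EUR", 0.0, 3.0) + rng.normal(0, 1, 60),
            "age": rng.normal(40, 10, 60),
        })
        p = covariate_ancestry_assoc(factors, groups)
        assert p["ctrlPC1"] < 1e-4
        assert p["age"] > 0.001

    def test_mixed_model_power_and_null(self):
        rng = np.random.default_rng(21)
        n_ind, reps = 20, 3
        ind = np.repeat([f"i{j}" for j in range(n_ind)], reps)
        groups = np.repeat(np.repeat(["a", "b"], n_ind // 2), reps)
        shift = np.where(groups == "a", 0.0, 3.0)
        y_alt = shift + np.repeat(rng.normal(0, 1, n_ind), reps) + rng.normal(0, 0.3, n_ind * reps)
        y_null = np.repeat(rng.normal(0, 1, n_ind), reps) + rng.normal(0, 0.3, n_ind * reps)
        p = covariate_ancestry_assoc(
            pd.DataFrame({"alt": y_alt, "null": y_null}), groups, ind, repeated=True
        )
        assert p["alt"] < 1e-4
        assert p["null"] > 0.01

    def test_exactly_duplicated_repeats_still_defined(self):
        rng = np.random.default_rng(22)
        n_ind, reps = 12, 2
        ind = np.repeat([f"i{j}" for j in range(n_ind)], reps)
        groups = np.repeat(np.repeat(["a", "b"], n_ind // 2), reps)
        y = np.repeat(rng.normal(0, 1, n_ind), reps)  # zero within-individual variance
        p = covariate_ancestry_assoc(pd.DataFrame({"f": y}), groups, ind, repeated=True)
        assert np.isfinite(p["f"])
        assert 0.0 <= p["f"] <= 1.0
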