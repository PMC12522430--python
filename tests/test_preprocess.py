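"""Masking, probe filtering, quantile normalization, betas, imputation."""

import numpy as np
import pandas as pd
import pytest

from methylancestry.containers import BetaMatrix
from methylancestry.preprocess import (
    compute_beta,
    filter_probes,
    impute_missing,
    mask_by_detection,
    quantile_normalize,
)

from conftest import make_intensity_set


class TestMasking:
    def test_all_below_threshold_is_identity(self, toy_iset):
        out = mask_by_detection(toy_iset)
        np.testing.assert_array_equal(out.meth.to_numpy(), toy_iset.meth.to_numpy())

    def test_single_failing_cell_masked_in_both_channels(self, toy_iset):
        toy_iset.detp.iloc[1, 2] = 1.0
        out = mask_by_detection(toy_iset)
        assert np.isnan(out.meth.iloc[1, 2]) and np.isnan(out.unmeth.iloc[1, 2])
        assert np.isnan(out.meth.to_numpy()).sum() == 1

    def test_hand_enumerated_positions(self):
        iset = make_intensity_set(n_probes=3, n_samples=3)
        cells = [(0, 0), (0, 2), (1, 1), (2, 2)]
        for i, j in cells:
            iset.detp.iloc[i, j] = 1e-10  # above the 1e-16 threshold
        out = mask_by_detection(iset)
        missing = {tuple(ij) for ij in np.argwhere(np.isnan(out.meth.to_numpy()))}
        assert missing == set(cells)


class TestProbeFiltering:
    def test_beadcount_rule_uses_strict_inequality(self):
        iset = make_intensity_set(n_probes=3, n_samples=20)
        iset.beadcount.iloc[0, :2] = 2.0  # 2/20 = 10% > 5% -> removed
        iset.beadcount.iloc[1, :1] = 2.0  # 1/20 = 5%, not > 5% -> kept
        out, report = filter_probes(iset)
        assert report.removed_beadcount == ["cg0"]
        assert list(out.probe_ids) == ["cg1", "cg2"]

    def test_callrate_rule_uses_strict_inequality(self):
        iset = make_intensity_set(n_probes=3, n_samples=10)
        iset.meth.iloc[0, 0] = np.nan  # 10%, not > 10% -> kept
        iset.meth.iloc[1, :2] = np.nan  # 20% > 10% -> removed
        out, report = filter_probes(iset)
        assert report.removed_callrate == ["cg1"]
        assert "cg0" in list(out.probe_ids)

    def test_double_failure_counted_once_under_beadcount(self):
        iset = make_intensity_set(n_probes=2, n_samples=10)
        iset.beadcount.iloc[0, :3] = 1.0
        iset.meth.iloc[0, :3] = np.nan
        _, report = filter_probes(iset)
        assert report.removed_beadcount == ["cg0"]
        assert report.removed_callrate == []

    def test_bookkeeping_accounts_for_every_probe(self):
        iset = make_intensity_set(n_probes=12, n_samples=10, seed=5)
        iset.beadcount.iloc[0, :2] = 1.0
        iset.meth.iloc[3, :4] = np.nan
        out, report = filter_probes(iset)
        assert report.n_input_probes == 12
        assert report.n_kept == len(out.probe_ids)
        assert report.n_kept + len(report.removed_ids) == 12
        assert not set(report.removed_beadcount) & set(report.removed_callrate)

    def test_all_removed_raises(self):
        iset = make_intensity_set(n_probes=2, n_samples=4)
        iset.beadcount.iloc[:, :] = 1.0
        with pytest.raises(ValueError, match="all probes removed"):
            filter_probes(iset)


class TestQuantileNormalization:
    def test_mean_of_order_statistics_by_hand(self):
        iset = make_intensity_set(n_probes=3, n_samples=2)
        iset.meth.iloc[:, 0] = [1.0, 2.0, 3.0]
        iset.meth.iloc[:, 1] = [4.0, 5.0, 6.0]
        out = quantile_normalize(iset)
        np.testing.assert_allclose(out.meth.iloc[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.meth.iloc[:, 1], [2.5, 3.5, 4.5])

    def test_identical_multisets_align_sorted_vectors(self):
        iset = make_intensity_set(n_probes=4, n_samples=2)
        iset.meth.iloc[:, 0] = [10.0, 30.0, 20.0, 40.0]
        iset.meth.iloc[:, 1] = [40.0, 20.0, 30.0, 10.0]
        out = quantile_normalize(iset)
        np.testing.assert_allclose(
            np.sort(out.meth.iloc[:, 0]), np.sort(out.meth.iloc[:, 1])
        )

    def test_constant_input_unchanged(self):
        iset = make_intensity_set(n_probes=3, n_samples=3)
        iset.meth.iloc[:, :] = 7.0
        out = quantile_normalize(iset)
        np.testing.assert_allclose(out.meth.to_numpy(), 7.0)

    def test_ranks_preserved_and_sorted_vectors_identical(self):
        iset = make_intensity_set(n_probes=50, n_samples=6, seed=9)
        out = quantile_normalize(iset)
        m_in, m_out = iset.meth.to_numpy(), out.meth.to_numpy()
        for j in range(6):
            assert (np.argsort(m_in[:, j]) == np.argsort(m_out[:, j])).all()
        ref = np.sort(m_out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(m_out[:, j]), ref, rtol=1e-12)

    def test_missing_entries_stay_missing(self):
        iset = make_intensity_set(n_probes=10, n_samples=4, seed=2)
        iset.meth.iloc[2, 1] = np.nan
        out = quantile_normalize(iset)
        assert np.isnan(out.meth.iloc[2, 1])
        assert np.isnan(out.meth.to_numpy()).sum() == 1

    def test_stratified_by_probe_type(self):
        iset = make_intensity_set(n_probes=6, n_samples=3, seed=4)
        types = pd.Series(
            ["II", "II", "II", "I_green", "I_green", "I_green"], index=iset.probe_ids
        )
        out = quantile_normalize(iset, probe_types=types, strata="by-type")
        m = out.meth.to_numpy()
        # each stratum's sorted vectors agree across samples
        for rows in (slice(0, 3), slice(3, 6)):
            block = m[rows]
            for j in range(1, 3):
                np.testing.assert_allclose(np.sort(block[:, j]), np.sort(block[:, 0]))


class TestBeta:
    def test_printed_arithmetic_cases(self, toy_iset):
        toy_iset.meth.iloc[0, 0] = 900.0
        toy_iset.unmeth.iloc[0, 0] = 0.0
        toy_iset.meth.iloc[1, 0] = 0.0
        toy_iset.meth.iloc[2, 0] = 0.0
        toy_iset.unmeth.iloc[2, 0] = 0.0
        beta = compute_beta(toy_iset)
        assert beta.values.iloc[0, 0] == pytest.approx(0.9)
        assert beta.values.iloc[1, 0] == 0.0
        assert beta.values.iloc[2, 0] == 0.0

    def test_monotone_in_m_and_u(self):
        m = np.linspace(0, 5000, 30)
        beta_m = m / (m + 1000 + 100)
        assert (np.diff(beta_m) > 0).all()
        u = np.linspace(0, 5000, 30)
        beta_u = 2000 / (2000 + u + 100)
        assert (np.diff(beta_u) < 0).all()
        assert ((beta_m >= 0) & (beta_m < 1)).all()

    def test_negative_intensity_rejected(self, toy_iset):
        toy_iset.meth.values[0, 0] = -5.0  # bypass container validation
        with pytest.raises(ValueError, match="negative"):
            compute_beta(toy_iset)


class TestImputation:
    def _beta(self, values):
        values = np.asarray(values, float)
        return BetaMatrix(
            pd.DataFrame(
                values,
                index=[f"p{i}" for i in range(values.shape[0])],
                columns=[f"s{j}" for j in range(values.shape[1])],
            )
        )

    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(0)
        beta = self._beta(rng.random((8, 5)))
        out = impute_missing(beta, seed=0)
        np.testing.assert_array_equal(out.values.to_numpy(), beta.values.to_numpy())

    def test_knn_imputes_neighbour_value_by_construction(self):
        vals = np.tile([0.2, 0.4, 0.6], (7, 1)).astype(float)
        vals[6] = [0.2, 0.4, 0.6]
        vals[6, 2] = np.nan
        vals[:6, 2] = 0.5  # all candidate donors carry 0.5 at the missing sample
        beta = self._beta(vals)
        out = impute_missing(beta, k=5, seed=0)
        assert out.values.iloc[6, 2] == pytest.approx(0.5)
        # observed entries untouched
        assert out.values.iloc[6, 0] == pytest.approx(0.2)

    def test_rank_one_matrix_recovered_accurately(self):
        rng = np.random.default_rng(42)
        probe_level = rng.uniform(0.2, 0.8, 60)
        sample_shift = rng.uniform(-0.1, 0.1, 25)
        truth = np.clip(probe_level[:, None] + sample_shift[None, :], 0, 1)
        vals = truth.copy()
        mask = rng.random(vals.shape) < 0.05
        mask[mask.all(axis=1), 0] = False  # keep every probe partly observed
        vals[mask] = np.nan
        out = impute_missing(self._beta(vals), k=5, seed=0)
        err = np.abs(out.values.to_numpy()[mask] - truth[mask])
        assert err.mean() < 0.05

    def test_fully_missing_probe_named(self):
        vals = np.full((3, 4), 0.5)
        vals[1] = np.nan
        with pytest.raises(ValueError, match="p1"):
            impute_missing(self._beta(vals), seed=0)

    def test_imputed_values_clipped_to_unit_interval(self):
        rng = np.random.default_rng(1)
        vals = rng.random((10, 6))
        vals[0, 0] = np.nan
        out = impute_missing(self._beta(vals), seed=0)
        assert 0.0 <= out.values.iloc[0, 0] <= 1.0


def test_pipeline_stage_determinism():
    """Identical inputs and thresholds give bit-identical beta matrices."""
    runs = []
    for _ in range(2):
        iset = make_intensity_set(n_probes=30, n_samples=8, seed=123)
        iset.detp.iloc[3, 4] = 1e-10
        iset = mask_by_detection(iset)
        iset, _ = filter_probes(iset)
        iset = quantile_normalize(iset)
        beta = impute_missing(compute_beta(iset), seed=7)
        runs.append(beta.values.to_numpy())
    np.testing.assert_array_equal(runs[0], runs[1])
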