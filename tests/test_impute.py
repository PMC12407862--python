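"""Missingness reporting, normalization, and the eight imputation methods."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spatomics as sp
from helpers import UNIT_SQUARE, grid_ds
from spatomics.impute import IMPUTATION_METHODS, SPATIAL_METHODS, STANDARD_METHODS


class TestMissingness:
    def test_count_ratio(self):
        ds = grid_ds(np.array([[1, np.nan, 3, 4], [np.nan, 6, 7, 8]]), UNIT_SQUARE)
        rep = sp.calc_missingness(ds)
        assert rep.overall == 0.25

    def test_fully_observed(self):
        ds = grid_ds(np.ones((2, 4)), UNIT_SQUARE)
        rep = sp.calc_missingness(ds)
        assert rep.overall == 0.0
        assert (rep.per_feature == 0).all() and (rep.per_sample == 0).all()

    def test_per_feature_fraction(self):
        ds = grid_ds(np.array([[1, np.nan, np.nan, 4]]), UNIT_SQUARE)
        assert sp.calc_missingness(ds).per_feature.iloc[0] == 0.5

    def test_overall_is_weighted_mean_of_per_feature(self, tissue_ds):
        masked = sp.apply_missingness(tissue_ds, rate=0.3, seed=5)
        rep = sp.calc_missingness(masked)
        assert rep.overall == pytest.approx(rep.per_feature.mean(), abs=1e-12)

    def test_unknown_assay(self, tiny_ds):
        with pytest.raises(KeyError):
            sp.calc_missingness(tiny_ds, "nope")


class TestMethodRegistry:
    def test_seven_standard_plus_one_spatial(self):
        assert len(STANDARD_METHODS) == 7
        assert len(SPATIAL_METHODS) == 1
        assert len(set(IMPUTATION_METHODS)) == 8
        assert "knn_spatial" in IMPUTATION_METHODS

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown imputation method"):
            sp.ImputationSpec(method="magic")

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sp.ImputationSpec(method="knn_spatial", k=0)


class TestSimpleMethods:
    @pytest.mark.parametrize("method, row, expected", [
        ("zero", [4.0, 8.0, np.nan], 0.0),
        ("half_feature_min", [4.0, 8.0, np.nan], 2.0),
        ("feature_mean", [1.0, 3.0, np.nan], 2.0),
        ("feature_median", [1.0, 2.0, 9.0, np.nan], 2.0),
        ("global_min", [4.0, 8.0, np.nan], 4.0),
    ])
    def test_fill_values(self, method, row, expected):
        coords = UNIT_SQUARE[: len(row)]
        ds = grid_ds(np.array([row]), coords)
        out = sp.impute(ds, method=method)
        assert out.assay("abundance").iloc[0, len(row) - 1] == expected

    def test_global_min_spans_features(self):
        ds = grid_ds(np.array([[5.0, np.nan, 6.0, 7.0], [1.0, 2.0, 3.0, 4.0]]),
                     UNIT_SQUARE)
        out = sp.impute(ds, method="global_min")
        assert out.assay("abundance").iloc[0, 1] == 1.0

    def test_all_missing_feature_left_missing_and_warned(self):
        ds = grid_ds(np.array([[np.nan] * 4, [1.0, 2.0, 3.0, 4.0]]), UNIT_SQUARE)
        with pytest.warns(UserWarning, match="no observed values"):
            out = sp.impute(ds, method="feature_mean")
        assert out.assay("abundance").iloc[0].isna().all()

    def test_provenance_recorded(self, tiny_ds):
        out = sp.impute(tiny_ds, method="zero")
        last = out.provenance[-1]
        assert last["op"] == "impute" and last["method"] == "zero"


class TestObservedPreservation:
    @pytest.mark.parametrize("method", IMPUTATION_METHODS)
    def test_every_method_preserves_observed_cells(self, tissue_ds, method):
        masked = sp.apply_missingness(tissue_ds, rate=0.2, seed=3)
        before = masked.assay("abundance").to_numpy()
        obs = ~np.isnan(before)
        out = sp.impute(masked, spec=sp.ImputationSpec(method=method, seed=1))
        after = out.assay("abundance").to_numpy()
        np.testing.assert_array_equal(after[obs], before[obs])
        assert not np.isnan(after).any()  # no all-missing features in this fixture


class TestDownshiftedGaussian:
    def test_draws_match_target_distribution(self):
        # one feature, many samples, mask a large block and compare the
        # imputed draws to Normal(mu - 1.8 sd, (0.3 sd)^2) by KS test
        rng = np.random.default_rng(0)
        n = 2 * 10_000
        row = rng.normal(25.0, 2.0, size=n)
        row_masked = row.copy()
        row_masked[10_000:] = np.nan
        coords = [(float(i % 200), float(i // 200)) for i in range(n)]
        ds = grid_ds(row_masked[None, :], coords)
        out = sp.impute(ds, method="downshifted_gaussian", seed=42, shift=1.8, scale=0.3)
        imputed = out.assay("abundance").to_numpy()[0, 10_000:]
        obs = row_masked[:10_000]
        mu, sd = obs.mean(), obs.std(ddof=1)
        stat, p = stats.kstest(imputed, "norm", args=(mu - 1.8 * sd, 0.3 * sd))
        assert p > 1e-3

    def test_same_seed_bit_reproducible(self, tissue_ds):
        masked = sp.apply_missingness(tissue_ds, rate=0.25, seed=9)
        a = sp.impute(masked, method="downshifted_gaussian", seed=7).assay("abundance")
        b = sp.impute(masked, method="downshifted_gaussian", seed=7).assay("abundance")
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())
        c = sp.impute(masked, method="downshifted_gaussian", seed=8).assay("abundance")
        assert not np.array_equal(c.to_numpy(), a.to_numpy())


class TestSpatialKnn:
    LAYOUT = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (5.0, 5.0)]

    def test_uniform_mean_of_two_nearest(self):
        ds = grid_ds(np.array([[np.nan, 10.0, 20.0, 99.0]]), self.LAYOUT)
        out = sp.spatial_knn_impute(ds, k=2, weighting="uniform")
        assert out.assay("abundance").iloc[0, 0] == 15.0

    def test_inverse_distance_equal_distances(self):
        ds = grid_ds(np.array([[np.nan, 10.0, 20.0, 99.0]]), self.LAYOUT)
        out = sp.spatial_knn_impute(ds, k=2, weighting="inverse_distance")
        assert out.assay("abundance").iloc[0, 0] == pytest.approx(15.0)

    def test_inverse_distance_weighted_mean(self):
        # neighbors at distance 1 (value 10) and 2 (value 20)
        coords = [(0.0, 0.0), (1.0, 0.0), (2.0, 0.0), (50.0, 50.0)]
        ds = grid_ds(np.array([[np.nan, 10.0, 20.0, 99.0]]), coords)
        out = sp.spatial_knn_impute(ds, k=2, weighting="inverse_distance")
        expected = (10.0 / 1 + 20.0 / 2) / (1 + 0.5)
        assert out.assay("abundance").iloc[0, 0] == pytest.approx(expected)

    def test_distance_zero_neighbor_dominates(self):
        coords = [(0.0, 0.0), (0.0, 0.0), (1.0, 0.0), (2.0, 0.0)]
        ds = grid_ds(np.array([[np.nan, 7.0, 100.0, 100.0]]), coords)
        out = sp.spatial_knn_impute(ds, k=3, weighting="inverse_distance")
        assert out.assay("abundance").iloc[0, 0] == 7.0

    def test_matches_exhaustive_distance_sort_oracle(self, tissue_ds):
        """Independent oracle: brute-force sort of centroid distances per cell."""
        masked = sp.apply_missingness(tissue_ds, rate=0.3, seed=21)
        k = 3
        out = sp.spatial_knn_impute(masked, k=k, weighting="uniform")
        a = masked.assay("abundance")
        cents = masked.centroids().to_numpy()
        vals = a.to_numpy()
        result = out.assay("abundance").to_numpy()
        rng = np.random.default_rng(2)
        miss_f, miss_s = np.nonzero(np.isnan(vals))
        pick = rng.choice(len(miss_f), size=50, replace=False)
        for f, s in zip(miss_f[pick], miss_s[pick]):
            d = np.sqrt(((cents - cents[s]) ** 2).sum(axis=1))
            cand = [(d[j], j) for j in range(len(d)) if j != s and not np.isnan(vals[f, j])]
            cand.sort(key=lambda t: t[0])
            expected = np.mean([vals[f, j] for _, j in cand[:k]])
            assert result[f, s] == pytest.approx(expected, rel=1e-12)

    def test_k_all_equals_feature_mean_of_observing(self, tissue_ds):
        masked = sp.apply_missingness(tissue_ds, rate=0.2, seed=4)
        n = len(masked.sample_ids)
        knn_all = sp.spatial_knn_impute(masked, k=n - 1, weighting="uniform")
        mean_imp = sp.impute(masked, method="feature_mean")
        np.testing.assert_allclose(knn_all.assay("abundance").to_numpy(),
                                   mean_imp.assay("abundance").to_numpy(),
                                   rtol=1e-10)

    def test_fewer_than_k_neighbors_warns_and_uses_available(self):
        ds = grid_ds(np.array([[np.nan, 10.0, 20.0, np.nan]]), self.LAYOUT)
        with pytest.warns(UserWarning, match="fewer than k"):
            out = sp.spatial_knn_impute(ds, k=3, weighting="uniform")
        assert out.assay("abundance").iloc[0, 0] == 15.0

    def test_lonlat_uses_great_circle(self):
        # query at (0, 0): 1 degree north (~111 km) is nearer than 3 degrees east
        coords = [(0.0, 0.0), (0.0, 1.0), (3.0, 0.0)]
        ds = grid_ds(np.array([[np.nan, 5.0, 50.0]]), coords)
        ds.coordinate_mode = "lonlat"
        out = sp.spatial_knn_impute(ds, k=1)
        assert out.assay("abundance").iloc[0, 0] == 5.0

    def test_requires_two_samples(self):
        ds = grid_ds(np.array([[np.nan]]), [(0.0, 0.0)])
        with pytest.raises(ValueError, match="at least 2"):
            sp.spatial_knn_impute(ds)


class TestSpatialKnnBeatsFeatureMean:
    def test_rmse_on_masked_cells_of_smooth_field(self):
        """Spatial kNN exploits the spatial structure a plain feature mean
        ignores: lower RMSE on masked cells across seeds."""
        wins = 0
        for seed in range(3):
            ds = sp.generate_tissue_fixture(sp.TissueFixtureParams(seed=seed))
            masked = sp.apply_missingness(ds, rate=0.2, seed=seed + 100)
            truth = masked.assays["abundance__complete"].to_numpy()
            holes = np.isnan(masked.assay("abundance").to_numpy())
            knn = sp.spatial_knn_impute(masked, k=4).assay("abundance").to_numpy()
            mean = sp.impute(masked, method="feature_mean").assay("abundance").to_numpy()
            rmse_knn = np.sqrt(np.mean((knn[holes] - truth[holes]) ** 2))
            rmse_mean = np.sqrt(np.mean((mean[holes] - truth[holes]) ** 2))
            wins += rmse_knn < rmse_mean
        assert wins >= 2


class TestMedianCenter:
    def test_columns_centered(self):
        ds = grid_ds(np.array([[1.0, 5.0], [2.0, np.nan], [3.0, 9.0]]),
                     UNIT_SQUARE[:2])
        out = sp.median_center(ds)
        a = out.assay("abundance")
        assert a["s0"].tolist() == [-1.0, 0.0, 1.0]
        assert a.loc["f0", "s1"] == -2.0 and a.loc["f2", "s1"] == 2.0
        assert np.isnan(a.loc["f1", "s1"])

    def test_idempotent(self, tissue_ds):
        once = sp.median_center(tissue_ds)
        twice = sp.median_center(once)
        np.testing.assert_allclose(twice.assay("abundance").to_numpy(),
                                   once.assay("abundance").to_numpy(), atol=1e-12)

    def test_empty_sample_warned(self):
        ds = grid_ds(np.array([[1.0, np.nan], [3.0, np.nan]]), UNIT_SQUARE[:2])
        with pytest.warns(UserWarning, match="no observed values"):
            out = sp.median_center(ds)
        assert out.assay("abundance")["s1"].isna().all()
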