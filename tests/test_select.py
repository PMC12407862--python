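"""Distance vectors, gradient correlation, Welch differential expression, BH."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spatomics as sp
from helpers import grid_ds


def welch_oracle(a, b):
    """Closed-form Welch t, Satterthwaite df, two-sided p via high-precision
    formulas, independent of the implementation path."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


class TestBhAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(sp.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert sp.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert (sp.bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_empty(self):
        assert sp.bh_adjust([]).size == 0

    def test_nan_passthrough(self):
        q = sp.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    def test_matches_statsmodels_and_dominates_p(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = sp.bh_adjust(pvals)
        expected = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, expected, rtol=1e-10)
        assert (q >= np.asarray(pvals) - 1e-15).all()
        assert (q <= 1.0).all()


class TestSampleDistances:
    def _ds(self, coords, labels):
        ds = grid_ds(np.zeros((1, len(coords))), coords)
        ds.sample_table["cat"] = labels
        return ds

    def test_three_four_five(self):
        ds = self._ds([(0.0, 0.0), (3.0, 4.0)], ["ref", "other"])
        d = sp.sample_distances(ds, "cat", "ref")
        assert d.iloc[1] == 5.0

    def test_reference_samples_at_zero(self):
        ds = self._ds([(2.0, 2.0), (3.0, 4.0)], ["ref", "other"])
        assert sp.sample_distances(ds, "cat", "ref").iloc[0] == 0.0

    def test_nearest_not_mean(self):
        ds = self._ds([(0.0, 0.0), (10.0, 0.0), (4.0, 0.0)], ["ref", "ref", "q"])
        assert sp.sample_distances(ds, "cat", "ref").iloc[2] == 4.0

    def test_lonlat_haversine(self):
        ds = self._ds([(0.0, 0.0), (0.0, 90.0)], ["ref", "q"])
        ds.coordinate_mode = "lonlat"
        quarter = math.pi / 2 * 6371.0  # pole-to-equator arc
        assert sp.sample_distances(ds, "cat", "ref").iloc[1] == pytest.approx(quarter, rel=1e-9)

    def test_no_reference_errors(self):
        ds = self._ds([(0.0, 0.0), (1.0, 0.0)], ["a", "b"])
        with pytest.raises(ValueError, match="no samples"):
            sp.sample_distances(ds, "cat", "zzz")


class TestDistanceBasedAnalysis:
    def _gradient_ds(self, n=20, slope=-0.7, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        coords = [(float(i), 0.0) for i in range(n)]
        d = np.arange(n, dtype=float)
        values = 10.0 + slope * d + noise * rng.normal(size=n)
        ds = grid_ds(values[None, :], coords)
        ds.sample_table["cat"] = ["ref"] + ["other"] * (n - 1)
        return ds

    def test_perfect_linear_anticorrelation_is_minus_one(self):
        ds = self._gradient_ds()
        _, table = sp.distance_based_analysis(ds, reference_column="cat",
                                              reference_value="ref")
        assert table["r"].iloc[0] == -1.0

    def test_constant_feature_flagged_undefined(self):
        ds = self._gradient_ds()
        ds.assays["abundance"].iloc[0, :] = 3.0
        _, table = sp.distance_based_analysis(ds, reference_column="cat",
                                              reference_value="ref")
        assert np.isnan(table["r"].iloc[0]) and np.isnan(table["fdr"].iloc[0])

    def test_reference_excluded_by_default(self):
        ds = self._gradient_ds(n=10)
        _, table = sp.distance_based_analysis(ds, reference_column="cat",
                                              reference_value="ref")
        assert table["n_used"].iloc[0] == 9
        _, table_inc = sp.distance_based_analysis(ds, reference_column="cat",
                                                  reference_value="ref",
                                                  include_reference=True)
        assert table_inc["n_used"].iloc[0] == 10

    def test_spearman_invariant_to_monotone_transform(self):
        ds = self._gradient_ds(noise=0.5, seed=3)
        _, t1 = sp.distance_based_analysis(ds, reference_column="cat",
                                           reference_value="ref", method="spearman")
        ds2 = ds.copy()
        ds2.assays["abundance"] = np.exp(ds2.assays["abundance"] / 3.0)
        _, t2 = sp.distance_based_analysis(ds2, reference_column="cat",
                                           reference_value="ref", method="spearman")
        assert t1["r"].iloc[0] == pytest.approx(t2["r"].iloc[0], abs=1e-12)
        assert t1["p_value"].iloc[0] == pytest.approx(t2["p_value"].iloc[0], rel=1e-9)

    def test_pearson_p_matches_t_transform(self):
        from scipy.stats import t as tdist

        ds = self._gradient_ds(noise=1.0, seed=5)
        _, table = sp.distance_based_analysis(ds, reference_column="cat",
                                              reference_value="ref")
        r, p, n = table["r"].iloc[0], table["p_value"].iloc[0], table["n_used"].iloc[0]
        t = r * math.sqrt((n - 2) / (1 - r ** 2))
        assert p == pytest.approx(2 * tdist.sf(abs(t), n - 2), rel=1e-9)

    def test_constant_distance_vector_errors(self):
        ds = grid_ds(np.random.default_rng(0).normal(size=(1, 4)),
                     [(0.0, 0.0), (1.0, 0.0), (1.0, 0.0), (1.0, 0.0)])
        ds.sample_table["cat"] = ["ref", "q", "q", "q"]
        with pytest.raises(ValueError, match="constant"):
            sp.distance_based_analysis(ds, reference_column="cat", reference_value="ref")

    def test_planted_gradient_ranks_first(self):
        """One planted gradient among 200 nulls should top the p-ranking."""
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            ds = sp.generate_tissue_fixture(sp.TissueFixtureParams(
                n_features=201, n_marker_features=0, n_gradient_features=1, seed=seed))
            _, table = sp.distance_based_analysis(
                ds, reference_column="region", reference_value="islet")
            hits += table.index[0] == "F0000"
        assert hits == n_seeds


class TestSpatialDiffEx:
    def _two_group_ds(self, a_vals, b_vals):
        vals = np.concatenate([a_vals, b_vals])[None, :]
        coords = [(float(i), 0.0) for i in range(vals.shape[1])]
        ds = grid_ds(vals, coords)
        ds.sample_table["grp"] = ["A"] * len(a_vals) + ["B"] * len(b_vals)
        return ds

    def test_welch_closed_form_example(self):
        ds = self._two_group_ds([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        _, table = sp.spatial_diff_ex(ds, category_column="grp", group_a="A", group_b="B")
        row = table.iloc[0]
        assert row["log_fc"] == pytest.approx(-3.0)
        assert row["t_stat"] == pytest.approx(-3.674, abs=5e-4)
        assert row["df"] == pytest.approx(4.0)

    def test_identical_groups_t_zero_p_one(self):
        ds = self._two_group_ds([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        _, table = sp.spatial_diff_ex(ds, category_column="grp", group_a="A", group_b="B")
        assert table["t_stat"].iloc[0] == pytest.approx(0.0)
        assert table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_zero_variance_both_groups_undefined(self):
        ds = self._two_group_ds([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        _, table = sp.spatial_diff_ex(ds, category_column="grp", group_a="A", group_b="B")
        assert np.isnan(table["t_stat"].iloc[0])
        assert np.isnan(table["fdr"].iloc[0])

    def test_sign_consistency_and_fdr_dominance(self, tissue_ds):
        _, table = sp.spatial_diff_ex(tissue_ds, category_column="region",
                                      group_a="islet", group_b="rest")
        ok = table.dropna(subset=["t_stat"])
        nz = ok[(ok["log_fc"] != 0) & (ok["t_stat"] != 0)]
        assert (np.sign(nz["log_fc"]) == np.sign(nz["t_stat"])).all()
        assert (ok["fdr"] >= ok["p_value"] - 1e-15).all()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 32 - 1))
    def test_matches_welch_oracle_on_random_groups(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(3, 9)), int(rng.integers(3, 9))
        a = rng.normal(0, 1 + rng.random(), size=na)
        b = rng.normal(rng.normal(), 1 + rng.random(), size=nb)
        ds = self._two_group_ds(a, b)
        _, table = sp.spatial_diff_ex(ds, category_column="grp", group_a="A", group_b="B")
        t, df, p = welch_oracle(a, b)
        assert table["t_stat"].iloc[0] == pytest.approx(t, abs=1e-10)
        assert table["df"].iloc[0] == pytest.approx(df, abs=1e-10)
        assert table["p_value"].iloc[0] == pytest.approx(p, abs=1e-10)

    def test_missing_values_omitted_pairwise(self):
        ds = self._two_group_ds([1.0, 2.0, 3.0, np.nan], [4.0, 5.0, 6.0])
        _, table = sp.spatial_diff_ex(ds, category_column="grp", group_a="A", group_b="B")
        assert table["n_a"].iloc[0] == 3
        t, df, p = welch_oracle([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert table["t_stat"].iloc[0] == pytest.approx(t, abs=1e-10)

    def test_insufficient_observed_flagged(self):
        ds = self._two_group_ds([1.0, np.nan, np.nan], [4.0, 5.0, 6.0])
        _, table = sp.spatial_diff_ex(ds, category_column="grp", group_a="A", group_b="B")
        assert np.isnan(table["p_value"].iloc[0])

    def test_small_group_errors(self):
        ds = self._two_group_ds([1.0], [4.0, 5.0, 6.0])
        with pytest.raises(ValueError, match="at least 2"):
            sp.spatial_diff_ex(ds, category_column="grp", group_a="A", group_b="B")

    def test_unknown_label_errors(self, tissue_ds):
        with pytest.raises(ValueError, match="no samples"):
            sp.spatial_diff_ex(tissue_ds, category_column="region",
                               group_a="liver", group_b="rest")

    def test_one_vs_rest_covers_all_levels(self, tissue_ds):
        results = sp.diff_ex_one_vs_rest(tissue_ds, category_column="region")
        assert set(results) == {"islet", "non_islet"}

    def test_global_null_type_one_error(self):
        """Under a pure-null fixture the Welch p < 0.05 rate sits near 0.05."""
        ds = sp.generate_tissue_fixture(sp.TissueFixtureParams(
            grid=(2, 5), n_features=1000, n_islet_rois=5,
            n_marker_features=0, n_gradient_features=0, delta=0.0, beta=0.0, seed=17))
        _, table = sp.spatial_diff_ex(ds, category_column="region",
                                      group_a="islet", group_b="rest")
        frac = float((table["p_value"] < 0.05).mean())
        half_width = 2.576 * math.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) < half_width
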