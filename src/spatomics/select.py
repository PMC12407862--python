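"""Feature selection: spatial-distance gradients and categorical contrasts.

Two fully data-driven routes for finding features of interest without prior
knowledge:

* :func:`distance_based_analysis` correlates each feature's abundance with
  the spatial distance of every ROI to a reference category (e.g. distance
  to the nearest islet), flagging features whose expression follows a
  spatial gradient.
* :func:`spatial_diff_ex` tests each feature for differential abundance
  between categorical ROI groups (e.g. islet vs non-islet) with a per
  feature Welch two-sample t-test.

Both append per-feature significance rankings to the dataset's feature
table under the analysis name, and return a tidy result table sorted by
p-value. Missing values are omitted pairwise — imputation is always an
explicit, logged, separate step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import SpatialOmicsDataset
from .distance import distances_to_points


def bh_adjust(p: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    q(i) = min_{j >= i} (m * p(j) / j) over the ascending p-ordering, capped
    at 1, returned in the input order. NaN entries are ignored (and returned
    as NaN); the effective m is the count of non-NaN p-values.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    qv = np.empty(m)
    qv[order] = ranked
    q[ok] = qv
    return q


def _log2_transform(values: np.ndarray) -> np.ndarray:
    """log2 with a half-minimum-positive offset so nonpositive cells stay finite.

    Intended for linear-scale inputs such as counts: zero cells become
    log2(c) with c = (smallest positive observed value) / 2; strictly
    positive matrices with no nonpositive cells are log2'd directly.
    """
    obs = values[~np.isnan(values)]
    if obs.size == 0:
        return values
    positive = obs[obs > 0]
    if positive.size == 0:
        raise ValueError("cannot log2-transform a matrix with no positive values")
    if obs.min() > 0:
        return np.log2(values)
    c = positive.min() / 2.0
    shift = c + max(0.0, -float(obs.min()))
    return np.log2(values + shift)


def sample_distances(ds: SpatialOmicsDataset, reference_column: str,
                     reference_value) -> pd.Series:
    """Distance of each sample to the nearest reference-category ROI centroid.

    Euclidean for planar coordinates, great-circle (km) for lonlat.
    Samples in the reference category are at distance 0 by construction.
    """
    if reference_column not in ds.sample_table.columns:
        raise KeyError(f"sample_table has no column {reference_column!r}")
    is_ref = (ds.sample_table[reference_column] == reference_value).to_numpy()
    if not is_ref.any():
        raise ValueError(f"no samples with {reference_column} == {reference_value!r}")
    cents = ds.centroids().to_numpy()
    d = distances_to_points(ds, cents[is_ref]).min(axis=1)
    d[is_ref] = 0.0
    return pd.Series(d, index=ds.sample_table.index, name="distance")


def distance_based_analysis(
    ds: SpatialOmicsDataset,
    assay: str = "abundance",
    reference_column: str = "category",
    reference_value=None,
    method: str = "pearson",
    include_reference: bool = False,
    name: str | None = None,
    linear_scale: bool = False,
) -> tuple[SpatialOmicsDataset, pd.DataFrame]:
    """Correlate each feature's abundance with distance to a reference category.

    Per feature, the Pearson or Spearman correlation between observed
    abundances and the sample distance vector is computed over usable
    samples. Reference samples (distance 0) are excluded by default since
    their distance-to-self anchors the fit; ``include_reference=True``
    overrides. Features with fewer than 3 usable samples or zero variance
    are flagged undefined (NaN statistics) and excluded from the BH FDR.

    Returns the augmented dataset and a table
    (feature_id, r, p_value, fdr, n_used) sorted by p-value.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    d_all = sample_distances(ds, reference_column, reference_value).to_numpy()
    use = np.ones(d_all.size, dtype=bool)
    if not include_reference:
        use = (ds.sample_table[reference_column] != reference_value).to_numpy()
        if use.sum() < 3:
            raise ValueError("fewer than 3 non-reference samples; set include_reference=True")
    d = d_all[use]
    if np.ptp(d) == 0:
        raise ValueError("distance vector is constant; no gradient definable")

    a = ds.assay(assay)
    values = a.to_numpy(dtype=float)[:, use]
    if linear_scale:
        values = _log2_transform(values)

    n_feat = values.shape[0]
    r = np.full(n_feat, np.nan)
    p = np.full(n_feat, np.nan)
    n_used = np.zeros(n_feat, dtype=int)
    for f in range(n_feat):
        x = values[f]
        obs = ~np.isnan(x)
        n = int(obs.sum())
        n_used[f] = n
        if n < 3 or np.ptp(x[obs]) == 0 or np.ptp(d[obs]) == 0:
            continue
        if method == "pearson":
            res = stats.pearsonr(x[obs], d[obs])
        else:
            res = stats.spearmanr(x[obs], d[obs])
        r[f], p[f] = float(res.statistic), float(res.pvalue)

    table = pd.DataFrame(
        {"r": r, "p_value": p, "fdr": bh_adjust(p), "n_used": n_used},
        index=a.index.rename("feature_id"),
    )
    out = ds.copy()
    name = name or f"gradient_{reference_column}_{reference_value}"
    out.set_stats(name, table)
    out.log_operation("distance_based_analysis", assay=assay, name=name, method=method,
                      reference_column=reference_column, reference_value=str(reference_value),
                      include_reference=include_reference)
    return out, table.sort_values("p_value")


def spatial_diff_ex(
    ds: SpatialOmicsDataset,
    assay: str = "abundance",
    category_column: str = "category",
    group_a=None,
    group_b="rest",
    name: str | None = None,
    equal_var: bool = False,
    linear_scale: bool = False,
) -> tuple[SpatialOmicsDataset, pd.DataFrame]:
    """Per-feature differential abundance between two categorical ROI groups.

    A Welch two-sample t-test (unequal variances; ``equal_var=True`` pools)
    on each feature's observed values, two-sided, with BH FDR across defined
    features. ``group_b="rest"`` contrasts group_a against all other
    samples. Abundances are assumed log2-scale, so the effect size
    ``log_fc = mean_A - mean_B`` is a log2 fold change; ``linear_scale=True``
    declares linear input, which is log2-transformed (half-minimum offset
    for nonpositive cells) before testing.

    Features with fewer than 2 observed values in either group, or zero
    variance in both, are flagged undefined and excluded from the FDR.

    Returns the augmented dataset and a table
    (feature_id, log_fc, t_stat, df, p_value, fdr, n_a, n_b) sorted by p.
    """
    if category_column not in ds.sample_table.columns:
        raise KeyError(f"sample_table has no column {category_column!r}")
    labels = ds.sample_table[category_column]
    in_a = (labels == group_a).to_numpy()
    if not in_a.any():
        raise ValueError(f"no samples with {category_column} == {group_a!r}")
    if isinstance(group_b, str) and group_b == "rest":
        in_b = ~in_a
    else:
        in_b = (labels == group_b).to_numpy()
        if not in_b.any():
            raise ValueError(f"no samples with {category_column} == {group_b!r}")
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    a = ds.assay(assay)
    values = a.to_numpy(dtype=float)
    if linear_scale:
        values = _log2_transform(values)
    va, vb = values[:, in_a], values[:, in_b]
    n_a = (~np.isnan(va)).sum(axis=1)
    n_b = (~np.isnan(vb)).sum(axis=1)

    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # near-constant features
        res = stats.ttest_ind(va, vb, axis=1, equal_var=equal_var, nan_policy="omit")
        log_fc = np.nanmean(va, axis=1) - np.nanmean(vb, axis=1)
    t = np.array(res.statistic, dtype=float)
    p = np.array(res.pvalue, dtype=float)
    df = np.array(res.df, dtype=float)

    defined = (n_a >= 2) & (n_b >= 2) & ~np.isnan(t)
    t[~defined] = np.nan
    p[~defined] = np.nan
    df[~defined] = np.nan
    log_fc = np.where((n_a > 0) & (n_b > 0), log_fc, np.nan)

    table = pd.DataFrame(
        {"log_fc": log_fc, "t_stat": t, "df": df, "p_value": p,
         "fdr": bh_adjust(p), "n_a": n_a, "n_b": n_b},
        index=a.index.rename("feature_id"),
    )
    out = ds.copy()
    name = name or f"diffex_{category_column}_{group_a}_vs_{group_b}"
    out.set_stats(name, table)
    out.log_operation("spatial_diff_ex", assay=assay, name=name,
                      category_column=category_column, group_a=str(group_a),
                      group_b=str(group_b), equal_var=equal_var)
    return out, table.sort_values("p_value")


def diff_ex_one_vs_rest(ds: SpatialOmicsDataset, assay: str = "abundance",
                        category_column: str = "category",
                        **kwargs) -> dict[str, pd.DataFrame]:
    """One-vs-rest contrasts for every level of a multi-category column,
    each independently FDR-corrected."""
    results = {}
    for level in pd.unique(ds.sample_table[category_column].dropna()):
        ds, table = spatial_diff_ex(ds, assay=assay, category_column=category_column,
                                    group_a=level, group_b="rest", **kwargs)
        results[str(level)] = table
    return results
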