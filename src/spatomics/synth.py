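"""Synthetic spatial omics fixtures with recorded ground truth.

Two generators emulate the two study designs every stage of the toolkit
must serve, at configurable scale and with truth labels stored in the
metadata tables so sensitivity and FDR are computable without any external
reference:

* :func:`generate_tissue_fixture` — a gridded tissue proteomics experiment:
  rectangular ROIs on an (rows x cols) grid, log2-scale Gaussian
  abundances, a contiguous block of "islet-like" ROIs in which marker
  features are elevated by a fixed log2 effect, and gradient features whose
  abundance decays linearly with distance from that block.
* :func:`generate_geospatial_fixture` — a soil-metagenome-like survey:
  sampling sites at lon/lat coordinates, two depths per site, KO
  (gene-family) presence counts drawn from a low-mean negative binomial,
  with a few KOs differentially abundant between a desert and a non-desert
  longitude band.

:func:`apply_missingness` masks cells completely at random (MCAR) or
abundance-dependently (MNAR, logistic in the within-feature z-score) to a
target overall rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ImageLayer, RoiGeometry, SpatialOmicsDataset
from .enrich import GeneSetCollection


@dataclass(frozen=True)
class TissueFixtureParams:
    """Parameters of the gridded tissue fixture.

    Units: the grid cell is the length unit (ROIs are 1x1 rects);
    abundances are log2 scale. ``delta`` is the marker elevation in islet
    ROIs (log2 units); ``beta`` the gradient slope per unit distance from
    the islet block; ``noise_sd`` the residual Gaussian sd.
    """

    grid: tuple[int, int] = (10, 10)
    n_features: int = 500
    n_islet_rois: int = 20
    n_marker_features: int = 50
    n_gradient_features: int = 50
    delta: float = 2.0
    beta: float = 0.5
    noise_sd: float = 0.5
    missing_rate: float = 0.0
    mechanism: str = "mcar"
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid
        if self.n_islet_rois >= rows * cols:
            raise ValueError(f"n_islet_rois={self.n_islet_rois} must be < grid size {rows * cols}")
        if self.n_marker_features + self.n_gradient_features > self.n_features:
            raise ValueError("n_marker_features + n_gradient_features exceeds n_features")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


def _islet_block(rows: int, cols: int, n: int) -> np.ndarray:
    """Pick a compact, contiguous block of n grid cells around the center."""
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = (rr - (rows - 1) / 2.0) ** 2 + (cc - (cols - 1) / 2.0) ** 2
    order = np.argsort(d2.ravel(), kind="stable")
    mask = np.zeros(rows * cols, dtype=bool)
    mask[order[:n]] = True
    return mask


def generate_tissue_fixture(params: TissueFixtureParams | None = None,
                            **kwargs) -> SpatialOmicsDataset:
    """Gridded tissue proteomics fixture with planted markers and gradients.

    abundance(f, s) = mu_f + delta * [f marker][s islet]
                      - beta * d(s) * [f gradient] + Normal(0, noise_sd^2),
    with baseline mu_f ~ Normal(20, 2^2) (log2-like scale) and d(s) the
    distance from s to the nearest islet-block centroid. Ground truth lands
    in feature_table (is_marker, is_gradient) and sample_table (is_islet,
    region, distance_to_islet). Identical seeds give identical datasets.
    """
    p = params or TissueFixtureParams(**kwargs)
    rng = np.random.default_rng(p.seed)
    rows, cols = p.grid
    n_samp = rows * cols

    islet = _islet_block(rows, cols, p.n_islet_rois)
    sample_ids = [f"roi_r{r:02d}c{c:02d}" for r in range(rows) for c in range(cols)]
    geometries = {}
    cents = np.empty((n_samp, 2))
    for i, (r, c) in enumerate((r, c) for r in range(rows) for c in range(cols)):
        geometries[sample_ids[i]] = RoiGeometry(kind="rect", x=float(c), y=float(r),
                                                width=1.0, height=1.0)
        cents[i] = (c + 0.5, r + 0.5)
    ref = cents[islet]
    d = np.sqrt(((cents[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    d[islet] = 0.0

    feature_ids = [f"F{i:04d}" for i in range(p.n_features)]
    is_marker = np.zeros(p.n_features, dtype=bool)
    is_marker[: p.n_marker_features] = True
    is_gradient = np.zeros(p.n_features, dtype=bool)
    is_gradient[p.n_marker_features: p.n_marker_features + p.n_gradient_features] = True

    mu = rng.normal(20.0, 2.0, size=p.n_features)
    values = mu[:, None] + rng.normal(0.0, p.noise_sd, size=(p.n_features, n_samp))
    values[is_marker] += p.delta * islet[None, :]
    values[is_gradient] -= p.beta * d[None, :]

    sample_table = pd.DataFrame(
        {"is_islet": islet,
         "region": np.where(islet, "islet", "non_islet"),
         "distance_to_islet": d,
         "row": np.repeat(np.arange(rows), cols),
         "col": np.tile(np.arange(cols), rows)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    feature_table = pd.DataFrame(
        {"is_marker": is_marker, "is_gradient": is_gradient, "baseline": mu},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    ds = SpatialOmicsDataset(
        assays={"abundance": pd.DataFrame(values, index=feature_ids, columns=sample_ids)},
        sample_table=sample_table,
        feature_table=feature_table,
        geometries=geometries,
        images={"tissue": _gradient_image(rows, cols)},
        coordinate_mode="planar",
    )
    ds.validate()
    ds.log_operation("generate_tissue_fixture", **{k: str(v) for k, v in vars(p).items()})
    if p.missing_rate > 0:
        ds = apply_missingness(ds, "abundance", mechanism=p.mechanism,
                               rate=p.missing_rate, seed=p.seed + 1)
    return ds


def _gradient_image(rows: int, cols: int, px_per_unit: int = 20) -> ImageLayer:
    """Flat diagonal-gradient grayscale backdrop covering the grid."""
    h, w = rows * px_per_unit, cols * px_per_unit
    yy, xx = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
    arr = (255 * (0.35 + 0.3 * (xx + yy) / 2.0)).astype(np.uint8)
    return ImageLayer(array=arr, units_per_pixel=1.0 / px_per_unit, x_offset=0.0, y_offset=0.0)


def generate_geospatial_fixture(
    n_sites: int = 54,
    n_depths: int = 2,
    n_kos: int = 300,
    n_up: int = 4,
    n_down: int = 2,
    seed: int = 0,
    bbox: tuple[float, float, float, float] = (-120.0, -80.0, 30.0, 45.0),
    desert_lon_cut: float = -105.0,
    base_mean_range: tuple[float, float] = (2.0, 10.0),
    effect_fold: float = 4.0,
    dispersion: float = 0.5,
) -> SpatialOmicsDataset:
    """Geospatial KO-count fixture: sites x depths, desert vs non-desert.

    Sites draw lon/lat uniformly in ``bbox`` (lon_min, lon_max, lat_min,
    lat_max); a site is "desert" when its longitude is west of
    ``desert_lon_cut``. Counts are negative binomial with per-KO means in
    ``base_mean_range`` and variance mu + dispersion * mu^2 — low means and
    low variance relative to MS abundances. ``n_up`` KOs have desert means
    multiplied by ``effect_fold`` and ``n_down`` divided by it; truth lands
    in feature_table (is_up, is_down) and sample_table (biome, depth).
    """
    if n_up + n_down > n_kos:
        raise ValueError(f"n_up + n_down = {n_up + n_down} exceeds n_kos = {n_kos}")
    rng = np.random.default_rng(seed)
    lon_min, lon_max, lat_min, lat_max = bbox
    # stratified draw: guarantee both biomes are populated
    n_desert_sites = max(1, int(round(n_sites * (desert_lon_cut - lon_min) / (lon_max - lon_min))))
    lon = np.concatenate([
        rng.uniform(lon_min, desert_lon_cut, size=n_desert_sites),
        rng.uniform(desert_lon_cut, lon_max, size=n_sites - n_desert_sites),
    ])
    lat = rng.uniform(lat_min, lat_max, size=n_sites)
    desert_site = lon < desert_lon_cut

    depths = ["top", "bottom"][:n_depths] if n_depths <= 2 else [f"d{i}" for i in range(n_depths)]
    sample_ids, site_of, depth_of = [], [], []
    for i in range(n_sites):
        for dep in depths:
            sample_ids.append(f"site{i:02d}_{dep}")
            site_of.append(i)
            depth_of.append(dep)
    site_of = np.asarray(site_of)
    is_desert = desert_site[site_of]

    ko_ids = [f"K{i:05d}" for i in range(n_kos)]
    is_up = np.zeros(n_kos, dtype=bool)
    is_up[:n_up] = True
    is_down = np.zeros(n_kos, dtype=bool)
    is_down[n_up: n_up + n_down] = True

    base_mu = rng.uniform(*base_mean_range, size=n_kos)
    mu = np.repeat(base_mu[:, None], len(sample_ids), axis=1)
    mu[np.ix_(is_up, is_desert)] *= effect_fold
    mu[np.ix_(is_down, is_desert)] /= effect_fold
    r = 1.0 / dispersion  # NB size parameter: var = mu + dispersion * mu^2
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)

    geometries = {
        sid: RoiGeometry(kind="point", x=float(lon[s]), y=float(lat[s]))
        for sid, s in zip(sample_ids, site_of)
    }
    sample_table = pd.DataFrame(
        {"site": site_of, "depth": depth_of,
         "biome": np.where(is_desert, "desert", "non_desert"),
         "is_desert": is_desert},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    feature_table = pd.DataFrame(
        {"is_up": is_up, "is_down": is_down, "base_mean": base_mu},
        index=pd.Index(ko_ids, name="feature_id"),
    )
    ds = SpatialOmicsDataset(
        assays={"ko_counts": pd.DataFrame(counts, index=ko_ids, columns=sample_ids)},
        sample_table=sample_table,
        feature_table=feature_table,
        geometries=geometries,
        coordinate_mode="lonlat",
    )
    ds.validate()
    ds.log_operation("generate_geospatial_fixture", n_sites=n_sites, n_depths=n_depths,
                     n_kos=n_kos, n_up=n_up, n_down=n_down, seed=seed)
    return ds


# ---------------------------------------------------------------------------
# missingness mechanisms

MNAR_STEEPNESS = 1.5  # fixed logistic slope; only the intercept is calibrated


def apply_missingness(ds: SpatialOmicsDataset, assay: str = "abundance",
                      mechanism: str = "mcar", rate: float = 0.2,
                      seed: int = 0) -> SpatialOmicsDataset:
    """Mask observed cells to a target overall missingness rate.

    ``mcar`` drops each cell independently with probability ``rate``.
    ``mnar`` drops cell (f, s) with probability
    sigmoid(alpha - 1.5 * z(f, s)) where z is the within-feature z-score,
    so low-abundance cells vanish preferentially (detection-limit
    missingness); alpha is calibrated by bisection so the expected overall
    rate equals ``rate``. The pre-masking values are kept in the dataset
    provenance-adjacent assay ``<assay>__complete`` for truth evaluation.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    if mechanism not in ("mcar", "mnar"):
        raise ValueError(f"mechanism must be 'mcar' or 'mnar', got {mechanism!r}")
    out = ds.copy()
    a = out.assays[assay]
    if rate == 0.0:
        return out
    values = a.to_numpy(dtype=float)
    obs = ~np.isnan(values)
    rng = np.random.default_rng(seed)
    if mechanism == "mcar":
        prob = np.full(values.shape, rate)
    else:
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(values, axis=1, keepdims=True)
            sd = np.nanstd(values, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = np.where(obs, (values - mu) / sd, 0.0)
        lo, hi = -30.0, 30.0
        for _ in range(80):  # bisect the intercept to hit the target rate
            alpha = (lo + hi) / 2.0
            mean_p = float(_sigmoid(alpha - MNAR_STEEPNESS * z)[obs].mean())
            if mean_p < rate:
                lo = alpha
            else:
                hi = alpha
        prob = _sigmoid(alpha - MNAR_STEEPNESS * z)
    mask = obs & (rng.random(values.shape) < prob)
    masked = values.copy()
    masked[mask] = np.nan
    out.assays[f"{assay}__complete"] = a
    out.assays[assay] = pd.DataFrame(masked, index=a.index, columns=a.columns)
    out.log_operation("apply_missingness", assay=assay, mechanism=mechanism,
                      rate=rate, seed=seed)
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_gmt_fixture(ds: SpatialOmicsDataset, n_sets: int = 20,
                         n_enriched: int = 2, seed: int = 0,
                         truth_column: str | None = None) -> GeneSetCollection:
    """Set library over a fixture's features: ``n_enriched`` sets are built
    mostly from the planted truth features (markers for the tissue fixture,
    up/down KOs for the geospatial one; override with ``truth_column``), so
    they are enriched by construction; the rest are random draws from the
    null features."""
    rng = np.random.default_rng(seed)
    ft = ds.feature_table
    feats = np.asarray(ft.index)
    false_col = pd.Series(False, index=ft.index)
    if truth_column is not None:
        truth = (ft[truth_column].astype(bool)
                 | ft.get("is_marker", false_col).astype(bool)
                 | ft.get("is_gradient", false_col).astype(bool))
        enriched_from = ft[truth_column].to_numpy(dtype=bool)
    elif "is_marker" in ft.columns:
        truth = ft["is_marker"].astype(bool) | ft.get("is_gradient", false_col).astype(bool)
        enriched_from = ft["is_marker"].to_numpy(dtype=bool)
    elif "is_up" in ft.columns:
        truth = ft["is_up"].astype(bool) | ft.get("is_down", false_col).astype(bool)
        enriched_from = truth.to_numpy(dtype=bool)
    else:
        raise ValueError("feature_table has no planted-truth columns (is_marker / is_up)")
    markers = feats[enriched_from]
    nulls = feats[~truth.to_numpy(dtype=bool)]
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    chunks = np.array_split(markers, max(1, n_enriched))
    for i in range(n_enriched):
        pad = rng.choice(nulls, size=5, replace=False)
        sets[f"marker_pathway_{i + 1}"] = list(chunks[i % len(chunks)]) + list(pad)
        desc[f"marker_pathway_{i + 1}"] = "enriched in planted markers by construction"
    for i in range(n_sets - n_enriched):
        size = int(rng.integers(10, 31))
        sets[f"random_set_{i + 1}"] = list(rng.choice(nulls, size=size, replace=False))
        desc[f"random_set_{i + 1}"] = "random null set"
    return GeneSetCollection(sets=sets, descriptions=desc, source="synthetic")
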