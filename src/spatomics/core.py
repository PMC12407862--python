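"""Spatial omics data container.

A :class:`SpatialOmicsDataset` binds one or more feature x sample abundance
matrices to sample metadata (regions of interest, ROIs), feature metadata,
per-sample spatial geometries and optional registered background images.
Coordinates are Cartesian (``planar``) or geographic (``lonlat``); all
downstream analyses are agnostic to coordinate magnitude, so the same code
serves micrometer-scale tissue grids and kilometer-scale geospatial surveys.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("spatomics")

#: strings interpreted as missing values when ingesting text matrices
MISSING_STRINGS = {"", "NA", "NaN", "null"}

#: reserved group key for samples with a missing value in a split column
UNASSIGNED_KEY = "unassigned"


class ValidationError(ValueError):
    """Raised when a dataset or its inputs violate the container contract."""


@dataclass(frozen=True)
class RoiGeometry:
    """Spatial footprint of one sample (ROI): a point or an axis-aligned rect.

    ``x, y`` are the point location, or the lower-left corner of the rect,
    in dataset units. Rect width/height must be strictly positive.
    """

    kind: str
    x: float
    y: float
    width: float | None = None
    height: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("point", "rect"):
            raise ValidationError(f"geometry kind must be 'point' or 'rect', got {self.kind!r}")
        if self.kind == "rect":
            if self.width is None or self.height is None:
                raise ValidationError("rect geometry requires width and height")
            if not (self.width > 0 and self.height > 0):
                raise ValidationError("rect width and height must be strictly positive")

    @property
    def centroid(self) -> tuple[float, float]:
        if self.kind == "point":
            return (float(self.x), float(self.y))
        return (float(self.x) + float(self.width) / 2.0, float(self.y) + float(self.height) / 2.0)


def roi_centroid(g: RoiGeometry) -> tuple[float, float]:
    """Centroid of a geometry in dataset units."""
    return g.centroid


@dataclass
class ImageLayer:
    """Raster image registered to dataset coordinates.

    ``units_per_pixel`` converts pixel extents to dataset units; the image
    origin (its bottom-left corner) sits at ``(x_offset, y_offset)`` in
    dataset units. The array is stored in conventional raster row order
    (row 0 = top of the image).
    """

    array: np.ndarray
    units_per_pixel: float = 1.0
    x_offset: float = 0.0
    y_offset: float = 0.0

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(left, right, bottom, top) in dataset units, for plotting."""
        h, w = self.array.shape[:2]
        return (
            self.x_offset,
            self.x_offset + w * self.units_per_pixel,
            self.y_offset,
            self.y_offset + h * self.units_per_pixel,
        )


@dataclass
class SpatialOmicsDataset:
    """Feature x sample abundance assays with spatial sample metadata.

    Attributes
    ----------
    assays
        Named feature x sample matrices (`pandas.DataFrame`, float values,
        NaN marks missing). All assays share the sample axis; each assay's
        feature index is an ordered subset of ``feature_table``'s index.
    sample_table
        Per-sample metadata indexed by unique sample id.
    feature_table
        Per-feature metadata indexed by unique feature id. Analyses append
        result columns here under a ``<name>__<stat>`` naming scheme.
    geometries
        One :class:`RoiGeometry` per sample.
    images
        Optional named :class:`ImageLayer` backgrounds.
    coordinate_mode
        ``"planar"`` (Euclidean distances) or ``"lonlat"`` (x=longitude,
        y=latitude; great-circle distances).
    provenance
        Append-only log of operations applied (method, parameters, seed).
    """

    assays: dict[str, pd.DataFrame]
    sample_table: pd.DataFrame
    feature_table: pd.DataFrame
    geometries: dict[str, RoiGeometry]
    images: dict[str, ImageLayer] = field(default_factory=dict)
    coordinate_mode: str = "planar"
    provenance: list[dict] = field(default_factory=list)

    # -- validation ------------------------------------------------------

    def validate(self) -> "SpatialOmicsDataset":
        if self.coordinate_mode not in ("planar", "lonlat"):
            raise ValidationError(f"unknown coordinate_mode {self.coordinate_mode!r}")
        for name, idx in (("sample", self.sample_table.index), ("feature", self.feature_table.index)):
            if idx.has_duplicates:
                dups = sorted(set(idx[idx.duplicated()]))
                raise ValidationError(f"duplicate {name} ids: {dups}")
            if any(str(i) == "" for i in idx):
                raise ValidationError(f"empty {name} id")
        samples = list(self.sample_table.index)
        for name, a in self.assays.items():
            if list(a.columns) != samples:
                raise ValidationError(f"assay {name!r} sample ordering does not match sample_table")
            if not a.index.isin(self.feature_table.index).all():
                extra = sorted(set(a.index) - set(self.feature_table.index))
                raise ValidationError(f"assay {name!r} features absent from feature_table: {extra[:5]}")
            if a.index.has_duplicates:
                raise ValidationError(f"assay {name!r} has duplicate feature ids")
        missing_geom = [s for s in samples if s not in self.geometries]
        if missing_geom:
            raise ValidationError(f"samples without geometry: {missing_geom}")
        extra_geom = [s for s in self.geometries if s not in set(samples)]
        if extra_geom:
            raise ValidationError(f"geometries for unknown samples: {extra_geom}")
        if self.coordinate_mode == "lonlat":
            for s, g in self.geometries.items():
                cx, cy = g.centroid
                if not (-180.0 <= cx <= 180.0 and -90.0 <= cy <= 90.0):
                    raise ValidationError(
                        f"sample {s!r}: lonlat centroid ({cx}, {cy}) out of range "
                        "(x in [-180, 180], y in [-90, 90])"
                    )
        return self

    # -- convenience -----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_table.index)

    def assay(self, name: str) -> pd.DataFrame:
        if name not in self.assays:
            raise KeyError(f"unknown assay {name!r}; have {sorted(self.assays)}")
        return self.assays[name]

    def centroids(self) -> pd.DataFrame:
        """Per-sample ROI centroids as a (sample x [x, y]) frame."""
        pts = [self.geometries[s].centroid for s in self.sample_ids]
        return pd.DataFrame(pts, index=pd.Index(self.sample_ids, name="sample_id"), columns=["x", "y"])

    def copy(self) -> "SpatialOmicsDataset":
        return SpatialOmicsDataset(
            assays={k: v.copy() for k, v in self.assays.items()},
            sample_table=self.sample_table.copy(),
            feature_table=self.feature_table.copy(),
            geometries=dict(self.geometries),
            images=dict(self.images),
            coordinate_mode=self.coordinate_mode,
            provenance=list(self.provenance),
        )

    def log_operation(self, op: str, **params) -> None:
        self.provenance.append({"op": op, **params})

    # -- analysis result columns ----------------------------------------

    def set_stats(self, name: str, stats: pd.DataFrame) -> None:
        """Append per-feature statistics under namespaced columns.

        Columns become ``<name>__<col>`` in ``feature_table``. Re-running an
        analysis under the same name replaces only its own columns; assays
        and sample_table are never touched.
        """
        prefix = f"{name}__"
        keep = [c for c in self.feature_table.columns if not str(c).startswith(prefix)]
        table = self.feature_table[keep]
        renamed = stats.rename(columns=lambda c: prefix + str(c))
        self.feature_table = table.join(renamed, how="left")

    def get_stats(self, name: str) -> pd.DataFrame:
        """Retrieve previously appended statistics for an analysis name."""
        prefix = f"{name}__"
        cols = [c for c in self.feature_table.columns if str(c).startswith(prefix)]
        if not cols:
            raise KeyError(f"no statistics stored under analysis name {name!r}")
        out = self.feature_table[cols].rename(columns=lambda c: str(c)[len(prefix):])
        return out.dropna(how="all")


# ---------------------------------------------------------------------------
# construction


def _coerce_numeric(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Coerce a raw matrix to float, mapping missing-value dialects to NaN.

    Returns the numeric frame and the count of cells that were unparseable
    or one of the recognised missing strings.
    """
    raw = table.astype(object)
    stripped = raw.map(lambda v: np.nan if (isinstance(v, str) and v.strip() in MISSING_STRINGS) else v)
    numeric = stripped.apply(pd.to_numeric, errors="coerce")
    n_missing = int(numeric.isna().sum().sum())
    return numeric.astype(float), n_missing


def _geometry_from_row(row: Mapping) -> RoiGeometry:
    kind = str(row["kind"]).strip().lower()
    def _opt(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return float(v)
    return RoiGeometry(kind=kind, x=float(row["x"]), y=float(row["y"]),
                       width=_opt("width"), height=_opt("height"))


def build_dataset(
    abundance: pd.DataFrame | str,
    samples: pd.DataFrame | str,
    features: pd.DataFrame | str,
    geometries: pd.DataFrame | str,
    images: Mapping[str, ImageLayer] | None = None,
    coordinate_mode: str = "planar",
    assay_name: str = "abundance",
) -> SpatialOmicsDataset:
    """Assemble and validate a dataset from tables (or TSV/CSV paths).

    The abundance matrix has feature ids in its first column (or index) and
    sample ids as its header. Sample and feature tables are reordered to
    match the matrix; unparseable numeric cells become NaN with a logged
    count. The geometry table needs columns ``sample_id, kind, x, y`` plus
    ``width, height`` for rects, and must cover every sample in the matrix.
    """
    from . import io  # local import to avoid cycle

    if isinstance(abundance, str):
        abundance = io.read_matrix(abundance)
    if isinstance(samples, str):
        samples = io.read_table(samples, index_col="sample_id")
    if isinstance(features, str):
        features = io.read_table(features, index_col="feature_id")
    if isinstance(geometries, str):
        geometries = io.read_table(geometries)

    samples = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    features = features.set_index("feature_id") if "feature_id" in features.columns else features
    samples.index = samples.index.astype(str)
    features.index = features.index.astype(str)
    abundance.index = abundance.index.astype(str)
    abundance.columns = abundance.columns.astype(str)

    for label, idx in (("sample", samples.index), ("feature", features.index),
                       ("matrix sample", abundance.columns), ("matrix feature", abundance.index)):
        if idx.has_duplicates:
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate {label} ids: {dups}")

    unknown_s = sorted(set(abundance.columns) - set(samples.index))
    if unknown_s:
        raise ValidationError(f"matrix samples absent from sample table: {unknown_s}")
    unknown_f = sorted(set(abundance.index) - set(features.index))
    if unknown_f:
        raise ValidationError(f"matrix features absent from feature table: {unknown_f}")

    numeric, n_missing = _coerce_numeric(abundance)
    if n_missing:
        logger.info("ingest: %d missing/unparseable cells mapped to NaN", n_missing)

    geom_table = geometries.copy()
    geom_table["sample_id"] = geom_table["sample_id"].astype(str)
    geom_map = {row["sample_id"]: _geometry_from_row(row) for _, row in geom_table.iterrows()}
    no_geom = [s for s in numeric.columns if s not in geom_map]
    if no_geom:
        raise ValidationError(f"samples without geometry rows: {no_geom}")

    ds = SpatialOmicsDataset(
        assays={assay_name: numeric},
        sample_table=samples.loc[numeric.columns],
        feature_table=features.loc[numeric.index],
        geometries={s: geom_map[s] for s in numeric.columns},
        images=dict(images or {}),
        coordinate_mode=coordinate_mode,
    )
    ds.validate()
    ds.log_operation("build_dataset", assay=assay_name, n_missing_ingested=n_missing)
    return ds


def split_dataset(ds: SpatialOmicsDataset, column: str) -> dict[str, SpatialOmicsDataset]:
    """Partition samples by a sample-metadata column.

    One dataset per distinct value; samples with a missing value in the
    column are grouped under :data:`UNASSIGNED_KEY`. The feature table is
    shared unchanged; the unions of the output sample sets reconstruct the
    input exactly.
    """
    if column not in ds.sample_table.columns:
        raise KeyError(f"sample_table has no column {column!r}")
    labels = ds.sample_table[column]
    keys = labels.astype(object).where(labels.notna(), UNASSIGNED_KEY)
    out: dict[str, SpatialOmicsDataset] = {}
    for key in pd.unique(keys):
        members = [s for s, k in zip(ds.sample_ids, keys) if k == key]
        sub = SpatialOmicsDataset(
            assays={n: a[members] for n, a in ds.assays.items()},
            sample_table=ds.sample_table.loc[members],
            feature_table=ds.feature_table,
            geometries={s: ds.geometries[s] for s in members},
            images=dict(ds.images),
            coordinate_mode=ds.coordinate_mode,
            provenance=list(ds.provenance),
        )
        sub.log_operation("split_dataset", column=column, value=str(key))
        out[str(key)] = sub.validate()
    return out
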