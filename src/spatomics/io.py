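"""Reading and writing datasets.

Text ingestion (TSV/CSV matrices and metadata tables), a single-file HDF5
on-disk container, PNG/TIFF background images, and export to the AnnData
``.h5ad`` dialect for ecosystem interop.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import ImageLayer, RoiGeometry, SpatialOmicsDataset


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample matrix: first column feature_id, header sample ids.

    Values are returned as-is (object dtype); missing-string handling happens
    during :func:`spatomics.core.build_dataset`.
    """
    df = pd.read_csv(path, sep=_sep(path), index_col=0, dtype=object, keep_default_na=False)
    df.index.name = "feature_id"
    return df


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    if index_col is not None and index_col in df.columns:
        df = df.set_index(index_col)
        df.index = df.index.astype(str)
    return df


def load_image(path: str | Path, units_per_pixel: float = 1.0,
               x_offset: float = 0.0, y_offset: float = 0.0) -> ImageLayer:
    from PIL import Image

    arr = np.asarray(Image.open(path))
    return ImageLayer(array=arr, units_per_pixel=units_per_pixel,
                      x_offset=x_offset, y_offset=y_offset)


# ---------------------------------------------------------------------------
# HDF5 container: groups /assays, /samples, /features, /geometries, /images

_STR = h5py.string_dtype(encoding="utf-8")


def _write_frame(group: h5py.Group, df: pd.DataFrame) -> None:
    group.create_dataset("index", data=np.array([str(i) for i in df.index], dtype=object), dtype=_STR)
    group.attrs["columns"] = json.dumps([str(c) for c in df.columns])
    for i, col in enumerate(df.columns):
        vals = df[col]
        if pd.api.types.is_numeric_dtype(vals) or pd.api.types.is_bool_dtype(vals):
            data = vals.to_numpy()
            if data.dtype == object:
                data = data.astype(float)
            group.create_dataset(f"col{i}", data=data)
        else:
            strs = vals.astype(object).where(vals.notna(), "").astype(str)
            group.create_dataset(f"col{i}", data=np.array(list(strs), dtype=object), dtype=_STR)


def _read_frame(group: h5py.Group) -> pd.DataFrame:
    index = pd.Index([s.decode() if isinstance(s, bytes) else s for s in group["index"][()]])
    columns = json.loads(group.attrs["columns"])
    data = {}
    for i, col in enumerate(columns):
        vals = group[f"col{i}"][()]
        if vals.dtype.kind in ("S", "O"):
            vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals], dtype=object)
        data[col] = vals
    return pd.DataFrame(data, index=index)


def save_h5(ds: SpatialOmicsDataset, path: str | Path) -> None:
    """Write a dataset to a single HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["coordinate_mode"] = ds.coordinate_mode
        f.attrs["provenance"] = json.dumps(ds.provenance, default=str)
        ga = f.create_group("assays")
        for name, a in ds.assays.items():
            g = ga.create_group(name)
            g.create_dataset("values", data=a.to_numpy(dtype=float))
            g.create_dataset("features", data=np.array([str(i) for i in a.index], dtype=object), dtype=_STR)
            g.create_dataset("samples", data=np.array([str(c) for c in a.columns], dtype=object), dtype=_STR)
        _write_frame(f.create_group("samples"), ds.sample_table)
        _write_frame(f.create_group("features"), ds.feature_table)
        gg = f.create_group("geometries")
        order = ds.sample_ids
        gg.create_dataset("sample_id", data=np.array(order, dtype=object), dtype=_STR)
        gg.create_dataset("kind", data=np.array([ds.geometries[s].kind for s in order], dtype=object), dtype=_STR)
        for fld in ("x", "y", "width", "height"):
            vals = [getattr(ds.geometries[s], fld) for s in order]
            gg.create_dataset(fld, data=np.array([np.nan if v is None else v for v in vals], dtype=float))
        gi = f.create_group("images")
        for name, img in ds.images.items():
            g = gi.create_group(name)
            g.create_dataset("array", data=img.array)
            g.attrs["units_per_pixel"] = img.units_per_pixel
            g.attrs["x_offset"] = img.x_offset
            g.attrs["y_offset"] = img.y_offset


def load_h5(path: str | Path) -> SpatialOmicsDataset:
    """Read a dataset written by :func:`save_h5`."""
    with h5py.File(path, "r") as f:
        assays = {}
        for name, g in f["assays"].items():
            feats = [s.decode() for s in g["features"][()]]
            samps = [s.decode() for s in g["samples"][()]]
            assays[name] = pd.DataFrame(g["values"][()], index=feats, columns=samps)
        sample_table = _read_frame(f["samples"])
        feature_table = _read_frame(f["features"])
        gg = f["geometries"]
        geometries = {}
        for i, sid in enumerate(s.decode() for s in gg["sample_id"][()]):
            w = gg["width"][i]
            h = gg["height"][i]
            geometries[sid] = RoiGeometry(
                kind=gg["kind"][i].decode(),
                x=float(gg["x"][i]), y=float(gg["y"][i]),
                width=None if np.isnan(w) else float(w),
                height=None if np.isnan(h) else float(h),
            )
        images = {}
        for name, g in f.get("images", {}).items():
            images[name] = ImageLayer(
                array=g["array"][()],
                units_per_pixel=float(g.attrs["units_per_pixel"]),
                x_offset=float(g.attrs["x_offset"]),
                y_offset=float(g.attrs["y_offset"]),
            )
        ds = SpatialOmicsDataset(
            assays=assays, sample_table=sample_table, feature_table=feature_table,
            geometries=geometries, images=images,
            coordinate_mode=str(f.attrs["coordinate_mode"]),
            provenance=json.loads(f.attrs.get("provenance", "[]")),
        )
    return ds.validate()


def to_anndata(ds: SpatialOmicsDataset, assay: str = "abundance"):
    """Export one assay as an AnnData (samples as obs, features as var).

    ROI centroids land in ``obsm["spatial"]`` following the spatial omics
    ecosystem convention.
    """
    import anndata as ad

    a = ds.assay(assay)
    adata = ad.AnnData(
        X=a.to_numpy(dtype=float).T,
        obs=ds.sample_table.loc[a.columns].copy(),
        var=ds.feature_table.loc[a.index].copy(),
    )
    adata.obsm["spatial"] = ds.centroids().loc[a.columns].to_numpy()
    adata.uns["coordinate_mode"] = ds.coordinate_mode
    return adata


def write_h5ad(ds: SpatialOmicsDataset, path: str | Path, assay: str = "abundance") -> None:
    to_anndata(ds, assay=assay).write_h5ad(path)
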