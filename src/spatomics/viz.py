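"""Scale-agnostic spatial visualization.

:func:`spatial_heatmap` paints each ROI at its geometry — filled rectangles
for gridded tissue, markers for point samples — colored by a per-sample
value (a feature's abundance, a derived pathway score, or any numeric
per-sample column), optionally over a registered background image or, for
geographic data, boundary polygons from a GeoJSON file. Figure dimensions
follow the coordinate *extent*, never the coordinate magnitude, so
micrometer tissue grids and kilometer-scale site maps render equivalently.

:func:`volcano_plot` is the standard effect-size vs significance scatter
for differential-abundance results, counting up/down features past the
cutoffs in its legend.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colors, patches
from matplotlib.cm import ScalarMappable

from .core import SpatialOmicsDataset


def _resolve_values(ds: SpatialOmicsDataset, value_source, assay: str) -> pd.Series:
    """Per-sample values: a feature id of an assay, a numeric sample_table
    column, or an explicit per-sample Series."""
    if isinstance(value_source, pd.Series):
        return value_source.reindex(ds.sample_ids).astype(float)
    a = ds.assays.get(assay)
    if a is not None and value_source in a.index:
        return a.loc[value_source].astype(float)
    if value_source in ds.sample_table.columns:
        col = ds.sample_table[value_source]
        if pd.api.types.is_numeric_dtype(col):
            return col.astype(float)
    raise KeyError(
        f"cannot resolve value source {value_source!r}: not a feature of assay "
        f"{assay!r} nor a numeric sample_table column"
    )


def _draw_geojson(ax, path: str | Path, **line_kw) -> None:
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    for feat in feats:
        geom = feat.get("geometry", feat)
        gtype, coords = geom["type"], geom["coordinates"]
        polys = [coords] if gtype == "Polygon" else coords if gtype == "MultiPolygon" else []
        for poly in polys:
            for ring in poly:
                xy = np.asarray(ring, dtype=float)
                ax.plot(xy[:, 0], xy[:, 1], **({"color": "0.4", "lw": 0.8} | line_kw))


def spatial_heatmap(
    ds: SpatialOmicsDataset,
    value_source,
    assay: str = "abundance",
    out: str | Path | None = None,
    palette: str | None = None,
    value_range: tuple[float, float] | None = None,
    background: str | None = None,
    boundaries: str | Path | None = None,
    label: bool = False,
    missing_color: str = "0.85",
    title: str | None = None,
):
    """Render per-sample values at their ROI geometries.

    Values outside ``value_range`` are clamped; samples with no value are
    drawn in ``missing_color``. The palette defaults to a sequential map,
    switching to a zero-centered diverging map when values span both signs
    (signed statistics read better that way). Returns the matplotlib
    figure; written to ``out`` (PNG or SVG by extension) when given.
    """
    vals = _resolve_values(ds, value_source, assay)
    finite = vals.dropna()
    if finite.empty:
        raise ValueError(f"all samples missing a value for {value_source!r}")

    lo, hi = value_range if value_range is not None else (float(finite.min()), float(finite.max()))
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    if palette is None:
        palette = "RdBu_r" if (finite.min() < 0 < finite.max()) else "viridis"
    if palette == "RdBu_r" and value_range is None and finite.min() < 0 < finite.max():
        lim = max(abs(lo), abs(hi))
        lo, hi = -lim, lim
    norm = colors.Normalize(vmin=lo, vmax=hi, clip=True)
    cmap = plt.get_cmap(palette)

    cents = ds.centroids()
    xs, ys = cents["x"], cents["y"]
    span_x = float(xs.max() - xs.min()) or 1.0
    span_y = float(ys.max() - ys.min()) or 1.0
    # figure shape tracks the extent aspect ratio, never the magnitude
    base = 6.0
    ratio = np.clip(span_y / span_x, 0.4, 2.5)
    fig, ax = plt.subplots(figsize=(base + 1.2, base * ratio))

    if background is not None:
        img = ds.images[background]
        ax.imshow(img.array, extent=img.extent, origin="upper",
                  interpolation="nearest", zorder=0,
                  cmap="gray" if img.array.ndim == 2 else None)
    if boundaries is not None:
        _draw_geojson(ax, boundaries)

    for sid in ds.sample_ids:
        g = ds.geometries[sid]
        v = vals.get(sid)
        color = missing_color if pd.isna(v) else cmap(norm(v))
        if g.kind == "rect":
            ax.add_patch(patches.Rectangle((g.x, g.y), g.width, g.height,
                                           facecolor=color, edgecolor="white",
                                           linewidth=0.5, zorder=2))
        else:
            ax.scatter([g.x], [g.y], c=[color], s=60, edgecolors="black",
                       linewidths=0.4, zorder=2)
        if label:
            cx, cy = g.centroid
            ax.annotate(str(sid), (cx, cy), ha="center", va="center",
                        fontsize=6, zorder=3)

    pad_x, pad_y = 0.05 * span_x, 0.05 * span_y
    xlim = (float(xs.min()) - pad_x, float(xs.max()) + pad_x)
    ylim = (float(ys.min()) - pad_y, float(ys.max()) + pad_y)
    for sid in ds.sample_ids:  # rects may extend past centroids
        g = ds.geometries[sid]
        if g.kind == "rect":
            xlim = (min(xlim[0], g.x), max(xlim[1], g.x + g.width))
            ylim = (min(ylim[0], g.y), max(ylim[1], g.y + g.height))
    ax.set_xlim(*xlim)
    ax.set_ylim(*ylim)
    ax.set_aspect("equal")
    if ds.coordinate_mode == "lonlat":
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
    else:
        ax.set_xlabel("x (dataset units)")
        ax.set_ylabel("y (dataset units)")
    ax.set_title(title or str(value_source))
    fig.colorbar(ScalarMappable(norm=norm, cmap=cmap), ax=ax, shrink=0.8,
                 label=str(value_source))
    if out is not None:
        fig.savefig(out, dpi=150, bbox_inches="tight")
    return fig


def volcano_plot(
    de: pd.DataFrame,
    p_cut: float = 0.05,
    fc_cut: float = 1.0,
    out: str | Path | None = None,
    p_col: str = "p_value",
    title: str | None = None,
):
    """Effect size vs significance scatter for a differential result table.

    x is ``log_fc``, y is -log10 of ``p_col`` (use ``p_col="fdr"`` to
    threshold on adjusted values). Features past both cutoffs are
    highlighted and counted in the legend as n_up / n_down; p = 0 entries
    are plotted at the largest finite -log10(p) + 1 with a warning.
    Returns (figure, n_up, n_down).
    """
    if de.empty:
        raise ValueError("empty differential result")
    d = de.dropna(subset=["log_fc", p_col])
    p = d[p_col].to_numpy(dtype=float)
    lfc = d["log_fc"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    if np.isinf(neglog).any():
        finite_max = neglog[np.isfinite(neglog)].max(initial=0.0)
        warnings.warn(f"volcano_plot: {int(np.isinf(neglog).sum())} zero p-value(s) "
                      f"plotted at {finite_max + 1:.2f}")
        neglog[np.isinf(neglog)] = finite_max + 1
    sig = p < p_cut
    up = sig & (lfc > fc_cut)
    down = sig & (lfc < -fc_cut)
    n_up, n_down = int(up.sum()), int(down.sum())

    fig, ax = plt.subplots(figsize=(6, 5))
    rest = ~(up | down)
    ax.scatter(lfc[rest], neglog[rest], s=12, c="0.6", label="not significant")
    ax.scatter(lfc[up], neglog[up], s=18, c="firebrick", label=f"n_up={n_up}")
    ax.scatter(lfc[down], neglog[down], s=18, c="steelblue", label=f"n_down={n_down}")
    ax.axhline(-np.log10(p_cut), ls="--", lw=0.8, c="0.3")
    ax.axvline(fc_cut, ls="--", lw=0.8, c="0.3")
    ax.axvline(-fc_cut, ls="--", lw=0.8, c="0.3")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel(f"-log10({p_col})")
    ax.set_title(title or "differential abundance")
    ax.legend(frameon=False, fontsize=8)
    if out is not None:
        fig.savefig(out, dpi=150, bbox_inches="tight")
    return fig, n_up, n_down
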