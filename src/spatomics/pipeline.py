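"""Configurable end-to-end workflows.

A pipeline is an ordered list of stages (ingest or fixture generation,
missingness report, imputation, differential expression or gradient
analysis, enrichment, plots) read from a YAML config. Every stage's name
and parameters are validated *before* anything runs; each produced file is
listed in a manifest with its stage, parameters hash, and content hash, so
an identical config and seed reproduces identical manifest hashes for
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrich, io, select, synth, viz
from .core import SpatialOmicsDataset, build_dataset
from .impute import ImputationSpec, calc_missingness, impute as impute_assay, median_center

logger = logging.getLogger("spatomics.pipeline")

STAGE_PARAMS: dict[str, set[str]] = {
    "ingest": {"abundance", "samples", "features", "geometries", "coordinate_mode", "assay_name"},
    "load": {"path"},
    "fixture_tissue": {"grid", "n_features", "n_islet_rois", "n_marker_features",
                       "n_gradient_features", "delta", "beta", "noise_sd",
                       "missing_rate", "mechanism", "seed"},
    "fixture_geo": {"n_sites", "n_depths", "n_kos", "n_up", "n_down", "seed"},
    "missingness": {"assay"},
    "impute": {"assay", "method", "k", "weighting", "shift", "scale", "seed"},
    "median_center": {"assay"},
    "diffex": {"assay", "category_column", "group_a", "group_b", "name",
               "equal_var", "linear_scale"},
    "gradient": {"assay", "reference_column", "reference_value", "method",
                 "include_reference", "name", "linear_scale"},
    "ora": {"gmt", "fdr_cut", "fc_cut", "min_size", "max_size", "diffex_name"},
    "gsea": {"gmt", "score", "n_perm", "seed", "weight", "min_size", "max_size"},
    "heatmap": {"value_source", "assay", "palette", "background", "boundaries", "label"},
    "volcano": {"p_cut", "fc_cut", "p_col"},
    "save": {"path"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline description: ordered stages, global seed, output dir."""

    stages: list[dict]
    seed: int = 0
    output_dir: str = "spatomics_out"

    def validate(self) -> "PipelineConfig":
        if not self.stages:
            raise ValueError("pipeline has no stages")
        for i, st in enumerate(self.stages):
            name = st.get("stage")
            if name not in STAGE_PARAMS:
                raise ValueError(f"stage {i}: unknown stage name {name!r}; "
                                 f"choose from {sorted(STAGE_PARAMS)}")
            params = st.get("params", {}) or {}
            if not isinstance(params, dict):
                raise ValueError(f"stage {i} ({name}): params must be a mapping")
            unknown = set(params) - STAGE_PARAMS[name]
            if unknown:
                raise ValueError(f"stage {i} ({name}): unknown parameters {sorted(unknown)}")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(
        stages=raw.get("stages", []),
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "spatomics_out")),
    ).validate()


def _hash_params(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class _State:
    ds: SpatialOmicsDataset | None = None
    diffex: dict[str, pd.DataFrame] = field(default_factory=dict)
    last_diffex: str | None = None
    gradient: pd.DataFrame | None = None
    gmt: enrich.GeneSetCollection | None = None


def run_pipeline(config: PipelineConfig) -> list[dict]:
    """Execute a validated pipeline; return the manifest of produced files.

    A stage failure aborts with the stage name; files from earlier stages
    are retained. Deterministic stages re-run with the same config and seed
    produce identical content hashes.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = _State()
    manifest: list[dict] = []

    for i, st in enumerate(config.stages):
        name = st["stage"]
        params = dict(st.get("params", {}) or {})
        try:
            produced = _run_stage(name, params, state, config, outdir, i)
        except Exception as exc:
            raise RuntimeError(f"pipeline aborted at stage {i} ({name}): {exc}") from exc
        for path in produced:
            manifest.append({"stage": name, "index": i, "path": str(path),
                             "params_hash": _hash_params(params),
                             "content_hash": _hash_file(Path(path))})
        logger.info("stage %d (%s): %d file(s)", i, name, len(produced))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _require_ds(state: _State) -> SpatialOmicsDataset:
    if state.ds is None:
        raise ValueError("no dataset loaded yet (run an ingest/fixture/load stage first)")
    return state.ds


def _resolve_gmt(params: dict, state: _State, config: PipelineConfig) -> enrich.GeneSetCollection:
    gmt = params.get("gmt", "fixture")
    if gmt == "fixture":
        return synth.generate_gmt_fixture(_require_ds(state), seed=config.seed)
    return enrich.read_gmt(gmt)


def _run_stage(name: str, params: dict, state: _State, config: PipelineConfig,
               outdir: Path, idx: int) -> list[Path]:
    if name == "ingest":
        state.ds = build_dataset(**params)
        path = outdir / f"{idx:02d}_dataset.h5"
        io.save_h5(state.ds, path)
        return [path]
    if name == "load":
        state.ds = io.load_h5(params["path"])
        return []
    if name == "fixture_tissue":
        params.setdefault("seed", config.seed)
        if "grid" in params:
            params["grid"] = tuple(params["grid"])
        state.ds = synth.generate_tissue_fixture(synth.TissueFixtureParams(**params))
        path = outdir / f"{idx:02d}_tissue_fixture.h5"
        io.save_h5(state.ds, path)
        return [path]
    if name == "fixture_geo":
        params.setdefault("seed", config.seed)
        state.ds = synth.generate_geospatial_fixture(**params)
        path = outdir / f"{idx:02d}_geo_fixture.h5"
        io.save_h5(state.ds, path)
        return [path]

    ds = _require_ds(state)
    default_assay = next(iter(ds.assays))

    if name == "missingness":
        rep = calc_missingness(ds, params.get("assay", default_assay))
        path = outdir / f"{idx:02d}_missingness.tsv"
        table = pd.DataFrame({"per_feature": rep.per_feature})
        table.to_csv(path, sep="\t")
        (outdir / f"{idx:02d}_missingness_overall.txt").write_text(f"{rep.overall:.6f}\n")
        return [path, outdir / f"{idx:02d}_missingness_overall.txt"]
    if name == "impute":
        params.setdefault("assay", default_assay)
        params.setdefault("seed", config.seed)
        assay = params.pop("assay")
        state.ds = impute_assay(ds, assay=assay, spec=ImputationSpec(**params))
        path = outdir / f"{idx:02d}_imputed.h5"
        io.save_h5(state.ds, path)
        return [path]
    if name == "median_center":
        state.ds = median_center(ds, params.get("assay", default_assay))
        return []
    if name == "diffex":
        params.setdefault("assay", default_assay)
        state.ds, table = select.spatial_diff_ex(ds, **params)
        key = params.get("name") or "diffex"
        state.diffex[key] = table
        state.last_diffex = key
        path = outdir / f"{idx:02d}_diffex.tsv"
        table.to_csv(path, sep="\t")
        return [path]
    if name == "gradient":
        params.setdefault("assay", default_assay)
        state.ds, table = select.distance_based_analysis(ds, **params)
        state.gradient = table
        path = outdir / f"{idx:02d}_gradient.tsv"
        table.to_csv(path, sep="\t")
        return [path]
    if name == "ora":
        if state.last_diffex is None:
            raise ValueError("ora stage needs a prior diffex stage")
        de = state.diffex[params.get("diffex_name") or state.last_diffex]
        defined = de.dropna(subset=["p_value"])
        fdr_cut = float(params.get("fdr_cut", 0.05))
        fc_cut = float(params.get("fc_cut", 0.0))
        selected = defined.index[(defined["fdr"] < fdr_cut) & (defined["log_fc"].abs() > fc_cut)]
        table = enrich.enrich_ora(
            set(selected), set(defined.index), _resolve_gmt(params, state, config),
            min_size=int(params.get("min_size", 5)), max_size=int(params.get("max_size", 500)))
        path = outdir / f"{idx:02d}_ora.tsv"
        table.to_csv(path, sep="\t", index=False)
        return [path]
    if name == "gsea":
        source = params.get("score", "gradient")
        if source == "gradient":
            if state.gradient is None:
                raise ValueError("gsea stage with score=gradient needs a prior gradient stage")
            scores = state.gradient["r"].dropna()
        else:
            if state.last_diffex is None:
                raise ValueError("gsea stage with score=diffex needs a prior diffex stage")
            scores = state.diffex[state.last_diffex]["t_stat"].dropna()
        table = enrich.enrich_gradient(
            scores, _resolve_gmt(params, state, config),
            n_perm=int(params.get("n_perm", 1000)),
            seed=int(params.get("seed", config.seed)),
            weight=float(params.get("weight", 1.0)),
            min_size=int(params.get("min_size", 5)),
            max_size=int(params.get("max_size", 500)))
        path = outdir / f"{idx:02d}_gsea.tsv"
        table.to_csv(path, sep="\t", index=False)
        return [path]
    if name == "heatmap":
        path = outdir / f"{idx:02d}_heatmap.png"
        params.setdefault("assay", default_assay)
        fig = viz.spatial_heatmap(ds, out=path, **params)
        import matplotlib.pyplot as plt
        plt.close(fig)
        return [path]
    if name == "volcano":
        if state.last_diffex is None:
            raise ValueError("volcano stage needs a prior diffex stage")
        path = outdir / f"{idx:02d}_volcano.png"
        fig, n_up, n_down = viz.volcano_plot(state.diffex[state.last_diffex], out=path, **params)
        import matplotlib.pyplot as plt
        plt.close(fig)
        counts = outdir / f"{idx:02d}_volcano_counts.json"
        counts.write_text(json.dumps({"n_up": n_up, "n_down": n_down}))
        return [path, counts]
    if name == "save":
        path = Path(params.get("path", outdir / f"{idx:02d}_dataset.h5"))
        io.save_h5(ds, path)
        return [path]
    raise AssertionError(name)  # pragma: no cover - validated upstream
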