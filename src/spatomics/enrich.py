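"""Set enrichment over feature-selection results.

Two statistics, matching the two selection routes:

* :func:`enrich_ora` — over-representation analysis: a hypergeometric
  upper-tail test of a selected feature list's overlap with each annotated
  set, against the universe of measured features (not the whole annotation
  space, to respect MS detectability bias).
* :func:`enrich_gradient` — rank-based enrichment of a signed per-feature
  statistic (a spatial-gradient correlation r, or a DE t): a weighted
  Kolmogorov–Smirnov running-sum enrichment score with a permutation null.

Set libraries are read from the tab-separated GMT format. For spatial
display, :func:`set_score_assay` collapses a set's leading-edge members to
a per-sample mean abundance, exposed as a derived assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import SpatialOmicsDataset
from .select import bh_adjust


@dataclass
class GeneSetCollection:
    """Named, deduplicated groups of feature identifiers."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str | None = None

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with a universe, dropping emptied sets."""
        sets = {}
        for name, members in self.sets.items():
            kept = [m for m in members if m in universe]
            if kept:
                sets[name] = kept
        return GeneSetCollection(sets=sets, descriptions=self.descriptions, source=self.source)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then members.

    Duplicate members within a line are dropped (first occurrence kept);
    a line with fewer than 3 fields, an empty member list, or a duplicate
    set name is an error naming the offending line.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(m for m in members if m))
            if not deduped:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def enrich_ora(
    selected: set[str] | list[str],
    universe: set[str] | list[str],
    sets: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in a selected list.

    With N = |universe|, K = |set ∩ universe|, n = |selected| and
    k = |set ∩ selected|, the p-value is the upper tail P(X >= k) of the
    hypergeometric distribution. Sets are restricted to the universe first;
    sets with K outside [min_size, max_size] are not tested. BH FDR over
    tested sets; rows sorted by p-value.
    """
    selected = set(selected)
    universe = set(universe)
    stray = sorted(selected - universe)
    if stray:
        raise ValueError(f"selected features not in universe: {stray[:10]}")
    if not universe:
        raise ValueError("universe is empty")

    N, n = len(universe), len(selected)
    rows = []
    for name, members in sets.sets.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        if K == 0 or not (min_size <= K <= max_size):
            continue
        hits = sorted(in_universe & selected)
        k = len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "n_set": K, "n_hit": k, "statistic": k,
                     "p_value": p, "direction": "na",
                     "leading_edge": ";".join(hits)})
    table = pd.DataFrame(rows, columns=["set", "n_set", "n_hit", "statistic",
                                        "p_value", "direction", "leading_edge"])
    if len(table):
        table["fdr"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
    return table[["set", "n_set", "n_hit", "statistic", "p_value", "fdr",
                  "direction", "leading_edge"]]


# ---------------------------------------------------------------------------
# gradient (rank-based) enrichment


def enrichment_score(scores_ranked: np.ndarray, member_mask: np.ndarray,
                     weight: float = 1.0) -> tuple[float, int]:
    """Weighted-KS running-sum enrichment score for one set.

    ``scores_ranked`` is the signed statistic sorted descending;
    ``member_mask`` flags set members in that ranked order. Hits advance the
    running sum by |score|^weight (normalized), misses retreat it by
    1/(N - set size); the ES is the extremum of the running sum. Returns
    (ES, index of the extremum).
    """
    hit_w = np.where(member_mask, np.abs(scores_ranked) ** weight, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all member scores zero: fall back to unweighted hits
        hit_w = member_mask.astype(float)
        denom = hit_w.sum()
    n_miss = member_mask.size - int(member_mask.sum())
    running = np.cumsum(hit_w / denom - (~member_mask) / n_miss)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def _perm_es(scores_ranked: np.ndarray, set_size: int, weight: float,
             n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Null |ES| distribution: permute which ranked positions are members."""
    N = scores_ranked.size
    hit_base = np.abs(scores_ranked) ** weight
    # each row: a random membership of the same size
    draws = rng.random((n_perm, N)).argpartition(set_size - 1, axis=1)[:, :set_size]
    mask = np.zeros((n_perm, N), dtype=bool)
    mask[np.arange(n_perm)[:, None], draws] = True
    hit = mask * hit_base[None, :]
    denom = hit.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    running = np.cumsum(hit / denom - (~mask) / (N - set_size), axis=1)
    return np.abs(running).max(axis=1)


def enrich_gradient(
    scores: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Rank-based set enrichment of a signed per-feature statistic.

    Features are ranked by score descending (ties broken by input order);
    each set gets a weighted-KS enrichment score. The null is built by
    permuting feature labels ``n_perm`` times with a fixed seed;
    p = (1 + #{|ES_perm| >= |ES|}) / (1 + n_perm), so permutation p-values
    are never 0. Direction is the sign of the ES. Sets covering the entire
    universe are excluded (degenerate running sum). BH FDR over tested sets.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if seed is None:
        raise ValueError("a seed is required for reproducible permutation p-values")
    values = np.asarray(scores, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("scores must be finite (drop undefined features first)")
    order = np.argsort(-values, kind="stable")
    ranked = values[order]
    feat_ranked = np.asarray(scores.index.astype(str))[order]
    pos = {f: i for i, f in enumerate(feat_ranked)}
    N = len(feat_ranked)

    rng = np.random.default_rng(seed)
    rows = []
    tested = sets.restrict(set(feat_ranked))
    for name, members in tested.sets.items():
        K = len(members)
        if not (min_size <= K <= max_size) or K >= N:
            continue
        mask = np.zeros(N, dtype=bool)
        mask[[pos[m] for m in members]] = True
        es, peak = enrichment_score(ranked, mask, weight=weight)
        null_abs = _perm_es(ranked, K, weight, n_perm, rng)
        p = float((1 + np.sum(null_abs >= abs(es))) / (1 + n_perm))
        if es >= 0:
            leading = feat_ranked[: peak + 1][mask[: peak + 1]]
        else:
            leading = feat_ranked[peak:][mask[peak:]]
        rows.append({"set": name, "n_set": K, "n_hit": len(leading),
                     "statistic": es, "p_value": p,
                     "direction": "up" if es > 0 else ("down" if es < 0 else "na"),
                     "leading_edge": ";".join(leading)})
    if not rows:
        raise ValueError("no sets within size bounds overlap the scored features")
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    return table[["set", "n_set", "n_hit", "statistic", "p_value", "fdr",
                  "direction", "leading_edge"]]


def set_score_assay(ds: SpatialOmicsDataset, enrichment: pd.DataFrame,
                    assay: str = "abundance",
                    name: str = "set_scores") -> SpatialOmicsDataset:
    """Per-sample pathway scores as a derived assay for spatial display.

    Each enriched set's sample-wise score is the mean abundance of its
    leading-edge members (falling back to all universe members when no
    leading edge is recorded), so enrichment results can be painted onto
    the ROI map with :func:`spatomics.viz.spatial_heatmap`.
    """
    a = ds.assay(assay)
    out = ds.copy()
    rows = {}
    for _, row in enrichment.iterrows():
        members = [m for m in str(row.get("leading_edge", "")).split(";") if m]
        members = [m for m in members if m in a.index]
        if not members:
            continue
        rows[row["set"]] = a.loc[members].mean(axis=0, skipna=True)
    if not rows:
        raise ValueError("no enriched set has members in the assay")
    score = pd.DataFrame(rows).T
    score = score[a.columns]
    out.assays[name] = score
    extra = out.feature_table.reindex(out.feature_table.index.union(score.index, sort=False))
    out.feature_table = extra
    out.log_operation("set_score_assay", assay=assay, derived=name, n_sets=len(score))
    return out
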