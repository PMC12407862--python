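"""Shared test construction helpers."""

import numpy as np
import pandas as pd

import spatomics as sp

UNIT_SQUARE = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)]


def grid_ds(values: np.ndarray, coords: list[tuple[float, float]],
            feature_ids=None) -> sp.SpatialOmicsDataset:
    """Minimal dataset from a value matrix and point coordinates."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_feat, n_samp = values.shape
    samples = [f"s{i}" for i in range(n_samp)]
    feats = feature_ids or [f"f{i}" for i in range(n_feat)]
    return sp.SpatialOmicsDataset(
        assays={"abundance": pd.DataFrame(values, index=feats, columns=samples)},
        sample_table=pd.DataFrame(index=pd.Index(samples, name="sample_id")),
        feature_table=pd.DataFrame(index=pd.Index(feats, name="feature_id")),
        geometries={s: sp.RoiGeometry("point", x, y)
                    for s, (x, y) in zip(samples, coords)},
    ).validate()
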