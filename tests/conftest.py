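import numpy as np
import pandas as pd
import pytest

from spatomics import RoiGeometry, SpatialOmicsDataset


@pytest.fixture
def tiny_ds() -> SpatialOmicsDataset:
    """3 features x 4 samples on a unit square, with two missing cells."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, np.nan, 7.0, np.nan],
         [0.5, 0.5, 0.5, 0.5]],
        index=["fA", "fB", "fC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    ds = SpatialOmicsDataset(
        assays={"abundance": values},
        sample_table=pd.DataFrame(
            {"group": ["a", "a", "b", "b"], "slice": ["A", "A", "B", "B"]},
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        ),
        feature_table=pd.DataFrame(
            {"pathway": ["p1", "p1", "p2"]},
            index=pd.Index(["fA", "fB", "fC"], name="feature_id"),
        ),
        geometries={
            "s1": RoiGeometry("point", 0.0, 0.0),
            "s2": RoiGeometry("point", 1.0, 0.0),
            "s3": RoiGeometry("point", 0.0, 1.0),
            "s4": RoiGeometry("point", 1.0, 1.0),
        },
    )
    return ds.validate()


@pytest.fixture(scope="session")
def tissue_ds():
    """Small tissue fixture shared by read-only tests."""
    from spatomics import TissueFixtureParams, generate_tissue_fixture

    return generate_tissue_fixture(TissueFixtureParams(
        grid=(8, 8), n_features=80, n_islet_rois=12,
        n_marker_features=10, n_gradient_features=10, seed=11))


@pytest.fixture(scope="session")
def geo_ds():
    from spatomics import generate_geospatial_fixture

    return generate_geospatial_fixture(n_sites=24, n_depths=2, n_kos=120,
                                       n_up=4, n_down=2, seed=7)
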