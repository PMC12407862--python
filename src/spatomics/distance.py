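"""Spatial distances between ROI centroids.

Planar datasets use Euclidean distance in dataset units; lonlat datasets use
great-circle (haversine) distance in kilometers on a sphere of radius
6371 km. Everything downstream only ever compares or weights distances, so
the unit choice is internally consistent.
"""

from __future__ import annotations

import numpy as np

from .core import SpatialOmicsDataset

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between (lon, lat) points in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def pairwise_distances(ds: SpatialOmicsDataset) -> np.ndarray:
    """Symmetric sample x sample centroid distance matrix (sample_table order)."""
    c = ds.centroids().to_numpy()
    if ds.coordinate_mode == "lonlat":
        lon = c[:, 0][:, None]
        lat = c[:, 1][:, None]
        return haversine_km(lon, lat, lon.T, lat.T)
    diff = c[:, None, :] - c[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def distances_to_points(ds: SpatialOmicsDataset, points: np.ndarray) -> np.ndarray:
    """Distance from each sample centroid to each of the given points.

    ``points`` is (m, 2) in dataset coordinates; returns (n_samples, m).
    """
    c = ds.centroids().to_numpy()
    points = np.asarray(points, dtype=float)
    if ds.coordinate_mode == "lonlat":
        return haversine_km(c[:, 0][:, None], c[:, 1][:, None],
                            points[:, 0][None, :], points[:, 1][None, :])
    diff = c[:, None, :] - points[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))
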