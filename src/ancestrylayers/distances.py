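"""Cultural, ecological and geographic distance matrices.

Jaccard distances on binary trait repertoires (shared absences ignored),
Gower dissimilarities on biome-composition tables, great-circle distances
between group centroids, and principal coordinates (shared with the
classical-MDS implementation in :mod:`popgen_stats`).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import haversine_distances

from .datatypes import DataFormatError, DistanceMatrix
from .popgen_stats import classical_mds

__all__ = [
    "jaccard_matrix",
    "gower_matrix",
    "greatcircle_matrix",
    "principal_coordinates",
]

EARTH_RADIUS_KM = 6371.0


def jaccard_matrix(traits: pd.DataFrame) -> DistanceMatrix:
    """Jaccard distance |A xor B| / |A or B| between trait repertoires.

    ``traits`` is a binary groups x traits presence/absence frame. Shared
    absences do not count. A pair whose union is empty gets distance 0 by
    convention (with a warning); this cannot occur with non-empty
    repertoires.
    """
    M = traits.to_numpy()
    if not np.isin(M, (0, 1)).all():
        raise DataFormatError("trait matrix must be binary")
    M = M.astype(float)
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, (union - inter) / np.where(union > 0, union, 1.0), 0.0)
    if (union[np.triu_indices(len(M), 1)] == 0).any():
        warnings.warn("pair(s) with empty trait union; distance set to 0",
                      stacklevel=2)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(traits.index), kind="jaccard")


def gower_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """Gower dissimilarity over mixed numeric/binary columns.

    Numeric variables contribute range-normalized absolute differences;
    binary (0/1) variables contribute simple mismatch (identical, since
    their range is 1). Variables with zero range are excluded with a
    warning, missing pairs are skipped per variable, and the contributions
    are averaged over the variables valid for each pair.
    """
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for j in range(p):
        col = X[:, j]
        valid = ~np.isnan(col)
        rng = np.nanmax(col) - np.nanmin(col) if valid.any() else 0.0
        if not np.isfinite(rng) or rng == 0.0:
            warnings.warn(f"variable {table.columns[j]!r} has zero range; excluded",
                          stacklevel=2)
            continue
        diff = np.abs(col[:, None] - col[None, :]) / rng
        ok = valid[:, None] & valid[None, :]
        num[ok] += diff[ok]
        cnt[ok] += 1.0
    if (cnt[np.triu_indices(n, 1)] == 0).any():
        raise DataFormatError("some pair has no jointly observed variable")
    d = num / np.maximum(cnt, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(table.index), kind="gower")


def greatcircle_matrix(coords: pd.DataFrame) -> DistanceMatrix:
    """Haversine great-circle distances (km) between group centroids.

    ``coords`` needs ``lat``/``lon`` columns in decimal degrees.
    """
    lat, lon = coords["lat"].to_numpy(float), coords["lon"].to_numpy(float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise DataFormatError("coordinates out of range")
    radians = np.radians(np.column_stack([lat, lon]))
    d = haversine_distances(radians) * EARTH_RADIUS_KM
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(coords.index), kind="geographic")


def principal_coordinates(dm: DistanceMatrix, k: int):
    """PCoA of a distance matrix: identical computation to classical MDS.

    Non-Euclidean inputs (e.g. Jaccard) are allowed; negative eigenvalues
    are reported and their axes excluded.
    """
    return classical_mds(dm, k)
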