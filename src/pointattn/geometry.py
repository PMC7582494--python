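"""Point-set containers, kNN grouping and fixed per-group feature maps.

A neighborhood is the center point itself plus its k-1 nearest neighbors
under exact Euclidean distance; the center is always stored first and
distance ties are broken by ascending point index so that grouping is
deterministic and permutation tests are well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "PointCloud", "NeighborhoodIndex", "GroupedFeature",
    "knn_group", "batch_knn", "edge_features",
    "geometric_descriptor", "spatial_descriptor",
]


@dataclass
class PointCloud:
    """N points x 3 coordinates with optional labels and extra channels.

    ``point_labels`` carries a per-point part id for segmentation;
    ``cloud_label`` a per-cloud class id for classification.
    """

    coords: np.ndarray
    extra_channels: np.ndarray | None = None
    point_labels: np.ndarray | None = None
    cloud_label: int | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an N x 3 array")
        if len(self.coords) < 1:
            raise ValueError("a point cloud needs at least one point")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")
        if self.extra_channels is not None:
            self.extra_channels = np.asarray(self.extra_channels, dtype=float)
            if self.extra_channels.shape[0] != len(self.coords):
                raise ValueError("extra_channels length must match coords")
        if self.point_labels is not None:
            self.point_labels = np.asarray(self.point_labels, dtype=np.int64)
            if self.point_labels.shape != (len(self.coords),):
                raise ValueError("point_labels length must match coords")

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def features(self) -> np.ndarray:
        """Coordinates concatenated with any extra channels (N x C)."""
        if self.extra_channels is None:
            return self.coords
        return np.concatenate([self.coords, self.extra_channels], axis=1)


@dataclass
class NeighborhoodIndex:
    """N x k table of group membership; row i starts with i itself."""

    indices: np.ndarray
    k: int
    metric_space: str = "coords"

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 2 or self.indices.shape[1] != self.k:
            raise ValueError("indices must be N x k")
        if self.metric_space not in ("coords", "features"):
            raise ValueError("metric_space must be 'coords' or 'features'")

    @property
    def n_points(self) -> int:
        return len(self.indices)


@dataclass
class GroupedFeature:
    """N x k x C' per-group feature values."""

    values: np.ndarray
    channels: int = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be N x k x C'")
        self.channels = self.values.shape[2]


def _knn_indices(feats: np.ndarray, k: int) -> np.ndarray:
    n = len(feats)
    d = cdist(feats, feats)
    # the center always heads its own group (strictly smallest pseudo-distance)
    np.fill_diagonal(d, -1.0)
    if k >= n:
        return np.argsort(d, axis=1, kind="stable")[:, :k]
    # top-k selection, then an exact sort of the k candidates; candidate
    # indices are pre-sorted so equal distances resolve to the smaller index
    cand = np.argpartition(d, k - 1, axis=1)[:, :k]
    cand.sort(axis=1)
    dsel = np.take_along_axis(d, cand, axis=1)
    order = np.argsort(dsel, axis=1, kind="stable")
    return np.take_along_axis(cand, order, axis=1)


def knn_group(features: np.ndarray, k: int, metric_space: str = "coords") -> NeighborhoodIndex:
    """Group each point with its k-1 nearest neighbors (center excluded
    from the neighbor count but stored first in its own row)."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be N x D")
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > len(features):
        raise ValueError("group size exceeds point count")
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    return NeighborhoodIndex(_knn_indices(features, k), k=k, metric_space=metric_space)


def batch_knn(feats: np.ndarray, k: int) -> np.ndarray:
    """kNN tables for a (B, N, D) stack, returned as (B, N, k) indices."""
    if k > feats.shape[1]:
        raise ValueError("group size exceeds point count")
    return np.stack([_knn_indices(f, k) for f in feats])


def _check_nbr(n: int, nbr: NeighborhoodIndex) -> np.ndarray:
    idx = nbr.indices
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError("neighborhood index out of range")
    if len(idx) != n:
        raise ValueError("neighborhood table does not match point count")
    return idx


def edge_features(point_feats: np.ndarray, nbr: NeighborhoodIndex) -> GroupedFeature:
    """EdgeConv input pairs (x_j - x_i, x_i) per group entry; C' = 2D."""
    x = np.asarray(point_feats, dtype=float)
    idx = _check_nbr(len(x), nbr)
    xj = x[idx]                      # N x k x D
    xi = np.broadcast_to(x[:, None, :], xj.shape)
    return GroupedFeature(np.concatenate([xj - xi, xi], axis=2))


def geometric_descriptor(coords: np.ndarray, nbr: NeighborhoodIndex) -> GroupedFeature:
    """10-channel group descriptor [x_i, x_j, x_j - x_i, ||x_j - x_i||]."""
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("coords must be N x 3")
    idx = _check_nbr(len(x), nbr)
    xj = x[idx]
    xi = np.broadcast_to(x[:, None, :], xj.shape)
    diff = xj - xi
    dist = np.linalg.norm(diff, axis=2, keepdims=True)
    return GroupedFeature(np.concatenate([xi, xj, diff, dist], axis=2))


def spatial_descriptor(coords: np.ndarray, nbr: NeighborhoodIndex) -> GroupedFeature:
    """9-channel descriptor [x_i, x_j, x_j - x_i]; the Euclidean-distance
    channel is omitted (its gradient is unstable at zero separation)."""
    full = geometric_descriptor(coords, nbr)
    return GroupedFeature(full.values[:, :, :9])
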