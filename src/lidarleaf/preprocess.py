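"""Point-cloud cleaning: background removal and the neighborhood filter.

Background removal drops returns from the pot/table/ground before any
expensive processing, using two cheap cues: reflectance (vegetation
returns low digital counts — anything above the threshold, default 20,
is non-plant) and position along the ground axis (the plant sits nearer
the scanner than the backdrop, so returns at or beyond a depth cut are
background).

The neighborhood filter both denoises and removes outliers in one pass.
For each point it counts the other points inside an axis-aligned box of
full side lengths ``(dx, dy, dz)`` centred on the point
(boundary-inclusive).  Points with at least ``min_neighbors`` such
neighbours are kept with their height (z) replaced by the mean height of
those neighbours; everything else — isolated returns, typically range
outliers — is discarded.  Counts and means are always taken against the
pass's *input* cloud (simultaneous update), which makes the result
independent of point order.  Two passes are chained by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .geometry import PointCloud

__all__ = ["BackgroundParams", "FilterParams", "remove_background",
           "neighborhood_filter"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class BackgroundParams:
    """Thresholds for background removal.

    max_range_cm:
        Ground-axis coordinate (scanner-frame depth, cm) at or beyond
        which a return is background.  None disables the depth cut.
    reflectance_threshold:
        Returns with reflectance above this digital count are non-plant.
        Vegetation reflects around 5 counts; 20 separates plant from
        background more robustly in practice.  None disables the cut.
    """

    max_range_cm: Optional[float] = None
    reflectance_threshold: Optional[float] = 20.0


@dataclass(frozen=True)
class FilterParams:
    """Neighborhood-filter parameters.

    window_cm:
        Full side lengths (dx, dy, dz) of the 3-D search box, cm.
    min_neighbors:
        Minimum neighbour count (the point itself excluded) for a point
        to survive.
    iterations:
        Number of chained passes; two passes refine the cloud enough for
        segmentation in typical scans.

    The 1 cm window and 4-neighbour defaults are starting points, not
    universal constants — suitable values change with leaf structure,
    leaf size and scan density.
    """

    window_cm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    min_neighbors: int = 4
    iterations: int = 2

    def __post_init__(self):
        w = tuple(float(v) for v in self.window_cm)
        if len(w) != 3 or any(v <= 0 for v in w):
            raise ParameterError("window_cm must be three positive side lengths")
        object.__setattr__(self, "window_cm", w)
        if self.min_neighbors < 1:
            raise ParameterError("min_neighbors must be a positive integer")
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")


def remove_background(
    cloud: PointCloud,
    params: BackgroundParams,
    ground_axis: str = "z",
    return_indices: bool = False,
):
    """Keep the plant: points passing every enabled criterion, in their
    original order.

    A point survives when its reflectance is <= the threshold (if set)
    and its ground-axis coordinate is strictly inside the foreground
    band, i.e. strictly less than ``max_range_cm`` (if set).
    """
    if params.max_range_cm is None and params.reflectance_threshold is None:
        raise ParameterError("background removal needs at least one criterion set")
    if ground_axis not in _AXES:
        raise ParameterError(f"ground_axis must be one of {sorted(_AXES)}")
    keep = np.ones(len(cloud), dtype=bool)
    if params.reflectance_threshold is not None:
        if cloud.reflectance is None:
            raise ParameterError(
                "reflectance threshold set but the cloud carries no reflectance"
            )
        keep &= cloud.reflectance <= params.reflectance_threshold
    if params.max_range_cm is not None:
        coord = (cloud.x_cm, cloud.y_cm, cloud.z_cm)[_AXES[ground_axis]]
        keep &= coord < params.max_range_cm
    idx = np.flatnonzero(keep)
    out = cloud.select(idx)
    return (out, idx) if return_indices else out


def _filter_pass(xyz: np.ndarray, params: FilterParams):
    """One simultaneous-update pass; returns (keep mask, refined z)."""
    n = xyz.shape[0]
    half = np.asarray(params.window_cm) / 2.0
    # Chebyshev search on window-normalised coordinates: the box
    # |dx|<=wx/2 etc. becomes an inf-norm ball of radius 1.
    scaled = xyz / half
    tree = cKDTree(scaled)
    # small tolerance keeps boundary pairs despite the division round-off
    pairs = tree.query_pairs(1.0 * (1 + 1e-12), p=np.inf, output_type="ndarray")
    counts = np.zeros(n, dtype=np.int64)
    zsum = np.zeros(n)
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        np.add.at(counts, i, 1)
        np.add.at(counts, j, 1)
        np.add.at(zsum, i, xyz[j, 2])
        np.add.at(zsum, j, xyz[i, 2])
    keep = counts >= params.min_neighbors
    z_new = np.where(keep, zsum / np.maximum(counts, 1), xyz[:, 2])
    return keep, z_new


def neighborhood_filter(
    cloud: PointCloud,
    params: FilterParams,
    return_indices: bool = False,
):
    """Run ``params.iterations`` passes of the neighborhood filter.

    Surviving points keep their x and y; z is replaced by the neighbour
    mean each pass.  Reflectance is carried through for kept points.
    With ``return_indices`` the indices (into the input cloud) of the
    survivors are returned alongside.
    """
    idx = np.arange(len(cloud))
    xyz = cloud.xyz.copy()
    for _ in range(params.iterations):
        if xyz.shape[0] == 0:
            break
        keep, z_new = _filter_pass(xyz, params)
        xyz[:, 2] = z_new
        xyz = xyz[keep]
        idx = idx[keep]
    refl = None if cloud.reflectance is None else cloud.reflectance[idx]
    out = PointCloud(xyz[:, 0], xyz[:, 1], xyz[:, 2], refl)
    return (out, idx) if return_indices else out
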