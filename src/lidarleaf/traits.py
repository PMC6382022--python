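"""Per-leaf trait extraction: length, width and surface area.

Length and width both follow the same midline procedure.  The leaf's
dominant planimetric axis is whichever of X or Y has the larger extent
(ties go to X).  A degree-2 polynomial ``dependent = a t^2 + b t + c``
is least-squares fitted with t the dominant-axis coordinate and the
dependent variable the other planimetric coordinate, capturing the
curved midline of a bent or curled leaf.  The fit is sampled at
``sample_count`` (default 50) equally spaced t-values spanning the
segment's extent inclusive of both extremes; each sample is snapped to
the nearest actual segment point in the planimetric plane, consecutive
duplicates are collapsed, and the trait is the sum of 3-D Euclidean
distances along the resulting polyline — an arc length that follows the
leaf through its out-of-plane bend.  Width runs the identical procedure
with the two planimetric axes swapped.

Surface area comes from a Delaunay triangulation of the planimetric
(X, Y) projection — the view a top-down scan sees — with each
triangle's area evaluated on the original 3-D vertices, so tilt and
bend contribute their true surface.  An unpruned triangulation of a
non-convex leaf fills concavities (a convex-hull bias); the optional
``prune_edge_cm`` drops triangles with any long edge before summation.
Pruning is off by default and recommended for lobed leaves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .errors import DegenerateSegmentError, FitError
from .geometry import PointCloud, triangle_areas_3d

__all__ = [
    "MidlineFit",
    "LeafTraits",
    "dominant_axis",
    "fit_midline",
    "midline_polyline",
    "leaf_length",
    "leaf_width",
    "leaf_area",
    "extract_traits",
]

_AX = {"x": 0, "y": 1}


@dataclass(frozen=True)
class MidlineFit:
    """Quadratic midline: dependent = a t^2 + b t + c along the
    dominant planimetric axis."""

    dominant_axis: Literal["x", "y"]
    a: float
    b: float
    c: float
    sample_count: int = 50

    def __post_init__(self):
        if not all(np.isfinite(v) for v in (self.a, self.b, self.c)):
            raise FitError("midline coefficients must be finite")
        if self.sample_count < 2:
            raise ValueError("sample_count must be >= 2")

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.a * t * t + self.b * t + self.c


@dataclass
class LeafTraits:
    """Per-leaf trait estimates (cm / cm^2); NaN marks a trait whose
    estimator failed on this segment."""

    leaf_label: int
    length_cm: float
    width_cm: float
    area_cm2: float


def dominant_axis(points: PointCloud) -> str:
    """'x' if the X extent is >= the Y extent, else 'y'."""
    if len(points) < 2:
        raise DegenerateSegmentError("dominant axis needs at least 2 points")
    ext_x = np.ptp(points.x_cm)
    ext_y = np.ptp(points.y_cm)
    return "x" if ext_x >= ext_y else "y"


def fit_midline(points: PointCloud, axis: str, sample_count: int = 50) -> MidlineFit:
    """Least-squares quadratic of the secondary planimetric coordinate
    against the dominant one."""
    if axis not in _AX:
        raise ValueError("axis must be 'x' or 'y'")
    if len(points) < 3:
        raise DegenerateSegmentError("midline fit needs at least 3 points")
    t = points.x_cm if axis == "x" else points.y_cm
    dep = points.y_cm if axis == "x" else points.x_cm
    if np.ptp(t) == 0:
        raise FitError(f"segment is degenerate along axis {axis!r}: zero extent")
    # centre t for conditioning; recentre the coefficients afterwards
    t0 = t.mean()
    try:
        ca, cb, cc = np.polyfit(t - t0, dep, 2)
    except np.linalg.LinAlgError as e:  # pragma: no cover - pathological input
        raise FitError(f"rank-deficient midline fit: {e}") from None
    a = ca
    b = cb - 2.0 * ca * t0
    c = cc - cb * t0 + ca * t0 * t0
    return MidlineFit(axis, float(a), float(b), float(c), sample_count)


def midline_polyline(points: PointCloud, fit: MidlineFit) -> np.ndarray:
    """Ordered (M, 3) polyline of actual segment points tracing the
    fitted midline.

    ``fit.sample_count`` t-values are spaced equally from the segment's
    minimum to its maximum along the dominant axis (both inclusive); the
    predicted (t, dependent) sample is mapped to the nearest segment
    point by planimetric distance so out-of-plane noise cannot hijack
    the polyline; consecutive duplicates collapse.
    """
    t_all = points.x_cm if fit.dominant_axis == "x" else points.y_cm
    dep_all = points.y_cm if fit.dominant_axis == "x" else points.x_cm
    t_s = np.linspace(t_all.min(), t_all.max(), fit.sample_count)
    samples = np.column_stack([t_s, fit.predict(t_s)])
    tree = cKDTree(np.column_stack([t_all, dep_all]))
    _, nearest = tree.query(samples)
    # collapse runs of the same snapped point (zero-length steps)
    keep = np.ones(nearest.size, dtype=bool)
    keep[1:] = nearest[1:] != nearest[:-1]
    return points.xyz[nearest[keep]]


def _polyline_arclength(poly: np.ndarray) -> float:
    if poly.shape[0] < 2:
        raise DegenerateSegmentError("midline polyline collapsed to a single point")
    return float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))


def leaf_length(points: PointCloud, sample_count: int = 50) -> float:
    """Arc length (cm) of the midline polyline along the dominant axis."""
    axis = dominant_axis(points)
    fit = fit_midline(points, axis, sample_count)
    return _polyline_arclength(midline_polyline(points, fit))


def leaf_width(points: PointCloud, sample_count: int = 50) -> float:
    """Identical procedure with the planimetric axes swapped: fit and
    sample along the secondary axis."""
    axis = dominant_axis(points)
    other = "y" if axis == "x" else "x"
    fit = fit_midline(points, other, sample_count)
    return _polyline_arclength(midline_polyline(points, fit))


def leaf_area(points: PointCloud, prune_edge_cm: Optional[float] = None) -> float:
    """Leaf surface area (cm^2): Delaunay triangles of the planimetric
    projection, summed as 3-D triangle areas; optionally long-edge
    pruned."""
    if len(points) < 3:
        raise DegenerateSegmentError("area needs at least 3 points")
    xy = np.column_stack([points.x_cm, points.y_cm])
    try:
        tri = Delaunay(xy)
    except QhullError as e:
        raise DegenerateSegmentError(
            f"planimetric projection is degenerate (collinear?): {e}"
        ) from None
    if tri.simplices.size == 0:
        raise DegenerateSegmentError("triangulation produced no triangles")
    xyz = points.xyz
    a = xyz[tri.simplices[:, 0]]
    b = xyz[tri.simplices[:, 1]]
    c = xyz[tri.simplices[:, 2]]
    if prune_edge_cm is not None:
        e = np.column_stack([
            np.linalg.norm(a - b, axis=1),
            np.linalg.norm(b - c, axis=1),
            np.linalg.norm(c - a, axis=1),
        ])
        keep = np.all(e <= prune_edge_cm, axis=1)
        a, b, c = a[keep], b[keep], c[keep]
    return float(np.sum(triangle_areas_3d(a, b, c)))


def extract_traits(
    points: PointCloud,
    label: int,
    sample_count: int = 50,
    prune_edge_cm: Optional[float] = None,
) -> LeafTraits:
    """Run all three estimators on one segment.

    A failing estimator marks its trait NaN and emits a warning rather
    than aborting the pipeline, so one degenerate segment cannot sink a
    whole scan's report.
    """
    out = {}
    for name, fn in (
        ("length_cm", lambda: leaf_length(points, sample_count)),
        ("width_cm", lambda: leaf_width(points, sample_count)),
        ("area_cm2", lambda: leaf_area(points, prune_edge_cm)),
    ):
        try:
            out[name] = fn()
        except (DegenerateSegmentError, FitError) as e:
            warnings.warn(f"segment {label}: {name} failed: {e}", stacklevel=2)
            out[name] = float("nan")
    return LeafTraits(leaf_label=label, **out)
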