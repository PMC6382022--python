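"""Scanner geometry and polar-to-Cartesian conversion.

Two scanner layouts are supported:

``pan_tilt``
    A single-beam rangefinder on a two-servo head.  Each grid cell holds
    the polar range ``rho`` measured at a vertical (azimuth) angle ``phi``
    — one per grid row — and a horizontal (elevation) angle ``theta`` —
    one per grid column.  Cartesian coordinates in centimetres are::

        X = rho * cos(phi)
        Y = rho * sin(phi) * cos(theta)
        Z = rho * sin(phi) * sin(theta)

    Note on the second and third factors: writing both sweep angles as
    ``phi`` would collapse the horizontal sweep onto a single vertical
    plane, so the horizontal factor must be the elevation angle
    ``theta``.  This module uses ``theta`` throughout.

``line_rail``
    A 2-D line scanner translated along a rail at constant speed.  The
    rail position supplies X directly — scan line ``i`` (0-based) sits at
    ``i * rail_speed_cm_s / scan_frequency_hz`` so the first line is at
    exactly 0 cm — and each beam angle ``phi`` (one per column, measured
    in the Y–Z plane from the +Y axis) converts as::

        Y = rho * cos(phi)
        Z = rho * sin(phi)

All angles are stored in degrees (scanner-native) and converted to
radians internally.  Points are emitted in row-major grid order; cells
with missing range produce no point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .errors import GeometryError

__all__ = [
    "ScanGeometry",
    "PointCloud",
    "Point3",
    "polar_to_cartesian_pan_tilt",
    "polar_to_cartesian_line_rail",
    "cartesian_to_polar_pan_tilt",
    "triangle_area_3d",
    "triangle_areas_3d",
]

Point3 = np.ndarray  # shape (3,) float, centimetres


def _as_angle_vector(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).ravel()
    if a.size < 1 or not np.all(np.isfinite(a)):
        raise GeometryError(f"{name} must be a non-empty finite vector")
    if a.size > 1:
        d = np.diff(a)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise GeometryError(f"{name} must be strictly monotonic")
    return a


@dataclass(frozen=True)
class ScanGeometry:
    """Geometry of one scan.

    Parameters
    ----------
    mode:
        ``"pan_tilt"`` or ``"line_rail"``.
    azimuth_deg:
        Per-row vertical angles phi (degrees); pan-tilt only.
    elevation_deg:
        Per-column angles (degrees): horizontal sweep theta for
        pan-tilt, in-plane beam angle phi for line-rail.
    rail_speed_cm_s, scan_frequency_hz:
        Rail kinematics; required for line-rail.  Their ratio is the
        spacing between consecutive scan lines along X.
    """

    mode: Literal["pan_tilt", "line_rail"]
    elevation_deg: np.ndarray
    azimuth_deg: Optional[np.ndarray] = None
    rail_speed_cm_s: Optional[float] = None
    scan_frequency_hz: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(
            self, "elevation_deg", _as_angle_vector(self.elevation_deg, "elevation_deg")
        )
        if self.mode == "pan_tilt":
            if self.azimuth_deg is None:
                raise GeometryError("pan_tilt geometry requires azimuth_deg")
            object.__setattr__(
                self, "azimuth_deg", _as_angle_vector(self.azimuth_deg, "azimuth_deg")
            )
            for name, v in (("azimuth_deg", self.azimuth_deg),
                            ("elevation_deg", self.elevation_deg)):
                if np.ptp(v) > 180.0:
                    raise GeometryError(f"pan_tilt {name} span exceeds 180 degrees")
        elif self.mode == "line_rail":
            if self.rail_speed_cm_s is None or self.scan_frequency_hz is None:
                raise GeometryError(
                    "line_rail geometry requires rail_speed_cm_s and scan_frequency_hz"
                )
            if self.rail_speed_cm_s <= 0 or self.scan_frequency_hz <= 0:
                raise GeometryError("rail speed and scan frequency must be positive")
        else:
            raise GeometryError(f"unknown scan mode {self.mode!r}")

    @property
    def line_spacing_cm(self) -> float:
        """Distance between consecutive scan lines along the rail (cm)."""
        if self.mode != "line_rail":
            raise GeometryError("line spacing is defined for line_rail mode only")
        return self.rail_speed_cm_s / self.scan_frequency_hz

    def expected_columns(self) -> int:
        return int(self.elevation_deg.size)

    def expected_rows(self) -> Optional[int]:
        """Row count implied by the geometry; None when the grid decides
        (line-rail rows are however many lines the rail produced)."""
        if self.mode == "pan_tilt":
            return int(self.azimuth_deg.size)
        return None


@dataclass
class PointCloud:
    """N Cartesian points in centimetres with optional per-point reflectance.

    The common currency of the pipeline: every stage consumes and
    produces one of these.  Coordinate vectors are parallel; reflectance,
    when present, is parallel too.
    """

    x_cm: np.ndarray
    y_cm: np.ndarray
    z_cm: np.ndarray
    reflectance: Optional[np.ndarray] = None

    def __post_init__(self):
        self.x_cm = np.asarray(self.x_cm, dtype=float).ravel()
        self.y_cm = np.asarray(self.y_cm, dtype=float).ravel()
        self.z_cm = np.asarray(self.z_cm, dtype=float).ravel()
        n = self.x_cm.size
        if self.y_cm.size != n or self.z_cm.size != n:
            raise ValueError("coordinate vectors must have equal length")
        for v in (self.x_cm, self.y_cm, self.z_cm):
            if v.size and not np.all(np.isfinite(v)):
                raise ValueError("coordinates must be finite")
        if self.reflectance is not None:
            self.reflectance = np.asarray(self.reflectance, dtype=float).ravel()
            if self.reflectance.size != n:
                raise ValueError("reflectance must be parallel to coordinates")

    def __len__(self) -> int:
        return int(self.x_cm.size)

    @property
    def xyz(self) -> np.ndarray:
        """(N, 3) coordinate array (copy-free column stack)."""
        return np.column_stack([self.x_cm, self.y_cm, self.z_cm])

    @classmethod
    def from_xyz(cls, xyz: np.ndarray, reflectance=None) -> "PointCloud":
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        return cls(xyz[:, 0], xyz[:, 1], xyz[:, 2], reflectance)

    def select(self, index) -> "PointCloud":
        """Sub-cloud at the given indices/mask, preserving order."""
        r = None if self.reflectance is None else self.reflectance[index]
        return PointCloud(self.x_cm[index], self.y_cm[index], self.z_cm[index], r)


def _present_cells(grid):
    rho = np.asarray(grid.range_cm, dtype=float)
    return rho, np.isfinite(rho)


def polar_to_cartesian_pan_tilt(grid) -> PointCloud:
    """Convert a pan-tilt polar grid to a Cartesian cloud (cm).

    One point per present cell, row-major order.  Reflectance is carried
    through per point when the grid has it.
    """
    if grid.geometry.mode != "pan_tilt":
        raise GeometryError("polar_to_cartesian_pan_tilt requires pan_tilt geometry")
    rho, present = _present_cells(grid)
    phi = np.deg2rad(grid.geometry.azimuth_deg)[:, None]
    theta = np.deg2rad(grid.geometry.elevation_deg)[None, :]
    x = rho * np.cos(phi)
    y = rho * np.sin(phi) * np.cos(theta)
    z = rho * np.sin(phi) * np.sin(theta)
    refl = None
    if grid.reflectance is not None:
        refl = np.asarray(grid.reflectance, dtype=float)[present]
    return PointCloud(x[present], y[present], z[present], refl)


def polar_to_cartesian_line_rail(grid) -> PointCloud:
    """Convert a line-rail polar grid to a Cartesian cloud (cm).

    X comes from the rail position of each scan line; Y and Z from the
    per-column beam angle.  Row-major emission order.
    """
    if grid.geometry.mode != "line_rail":
        raise GeometryError("polar_to_cartesian_line_rail requires line_rail geometry")
    rho, present = _present_cells(grid)
    n_rows = rho.shape[0]
    spacing = grid.geometry.line_spacing_cm
    phi = np.deg2rad(grid.geometry.elevation_deg)[None, :]
    x = np.broadcast_to((np.arange(n_rows) * spacing)[:, None], rho.shape)
    y = rho * np.cos(phi)
    z = rho * np.sin(phi)
    refl = None
    if grid.reflectance is not None:
        refl = np.asarray(grid.reflectance, dtype=float)[present]
    return PointCloud(x[present], y[present], z[present], refl)


def cartesian_to_polar_pan_tilt(x, y, z):
    """Inverse of the pan-tilt conversion: (X, Y, Z) -> (rho, phi, theta)
    in centimetres and degrees.  Valid for rho > 0 and 0 < phi < 180."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    rho = np.sqrt(x * x + y * y + z * z)
    phi = np.arccos(np.clip(np.divide(x, rho, out=np.zeros_like(rho),
                                      where=rho > 0), -1.0, 1.0))
    theta = np.arctan2(z, y)
    return rho, np.rad2deg(phi), np.rad2deg(theta)


def triangle_area_3d(a, b, c) -> float:
    """Area (cm^2) of the 3-D triangle ABC.

    Evaluated as half the root-sum-square of the three 3x3 determinants
    formed by the vertex coordinates in each pairwise coordinate plane
    (xy, yz, zx) with a row of ones — each determinant is twice the
    signed area of the triangle's projection onto that plane, and the
    three projections recombine to the true 3-D area.  Algebraically
    identical to half the cross-product magnitude ``|AB x AC| / 2``;
    degenerate (collinear) triangles return 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    d = np.empty(3)
    for k, (i, j) in enumerate(((0, 1), (1, 2), (2, 0))):
        d[k] = np.linalg.det(
            np.array([[a[i], b[i], c[i]], [a[j], b[j], c[j]], [1.0, 1.0, 1.0]])
        )
    return 0.5 * float(np.sqrt(np.sum(d * d)))


def triangle_areas_3d(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorised :func:`triangle_area_3d` over (N, 3) vertex arrays."""
    a = np.asarray(a, float).reshape(-1, 3)
    b = np.asarray(b, float).reshape(-1, 3)
    c = np.asarray(c, float).reshape(-1, 3)
    # 2x signed projected areas onto the xy, yz and zx planes
    d = np.empty((a.shape[0], 3))
    for k, (i, j) in enumerate(((0, 1), (1, 2), (2, 0))):
        d[:, k] = (
            a[:, i] * (b[:, j] - c[:, j])
            + b[:, i] * (c[:, j] - a[:, j])
            + c[:, i] * (a[:, j] - b[:, j])
        )
    return 0.5 * np.sqrt(np.sum(d * d, axis=1))
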