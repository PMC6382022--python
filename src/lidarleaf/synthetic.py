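"""Virtual scanner: mesh plant scenes with analytic ground truth.

No public LiDAR scans of single plants at centimetre scale come with
per-leaf trait annotations, so validation runs on synthetic scenes: a
set of triangle-meshed leaves above a high-reflectance ground plane,
ray-cast by a virtual scanner in either geometry (pan-tilt head or
line-rail) into exactly the polar grid format the pipeline ingests.

Leaves are elliptical planforms — length along the midline, an
elliptic width profile — optionally bent by a quadratic sag
``z = k * s**2`` along the midline, then yawed and translated into
place.  This is the minimal shape family that exercises every pipeline
stage: a curved midline for the quadratic fit, and an out-of-plane bend
that makes true surface area exceed projected area.  Ground truth is
analytic: length is the closed-form arc length of the bent midline,
width the maximal chord perpendicular to the midline (the planform
minor axis), and area the exact summed triangle area of the mesh the
rays actually hit.

The scene frame puts the scanner at the origin looking toward +Z, so Z
is scanner depth: leaves sit nearer (smaller Z), the ground plane
farther.  The noise model lives in range (polar) space where the sensor
noise physically arises: Gaussian range jitter, sparse large-offset
outlier returns, optional dropout of grazing-incidence beams, and
per-return reflectance jitter.  All randomness flows from one seeded
generator, so a given seed reproduces a scan bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import trimesh

from .errors import GeometryError, ParameterError
from .geometry import ScanGeometry
from .scan_io import GROUND_TRUTH_COLUMNS, PolarScanGrid
from .segmentation import LeafSegment

__all__ = [
    "LeafSpec",
    "SyntheticScene",
    "NoiseModel",
    "ScanDiagnostics",
    "make_leaf",
    "simulate_scan",
    "scene_ground_truth",
    "rail_geometry_for_scene",
    "pan_tilt_geometry_for_scene",
    "demo_scene",
    "match_segments_to_leaves",
    "count_detected_leaves",
    "scene_to_dict",
    "scene_from_dict",
]

# rail kinematics of the reference line scanner: 18.0724 cm/s at 360
# scans/s puts consecutive scan lines 0.0502 cm (~0.5 mm) apart
RAIL_SPEED_CM_S = 18.0724
SCAN_FREQUENCY_HZ = 360.0


@dataclass(frozen=True)
class LeafSpec:
    """Parameters of one synthetic leaf.

    length_cm, width_cm:
        Planform major/minor extents of the elliptical leaf.
    bend_coefficient:
        Quadratic sag k in z = k s^2 (1/cm) along the midline; 0 is a
        flat leaf.
    yaw_deg:
        Rotation of the planform about the depth (Z) axis.
    center:
        Leaf centre in scene coordinates (cm); z is scanner depth.
    reflectance_mean:
        Mean digital count of returns from this leaf; vegetation-like
        values sit well below the background threshold.
    """

    length_cm: float
    width_cm: float
    bend_coefficient: float = 0.0
    yaw_deg: float = 0.0
    center: Tuple[float, float, float] = (0.0, 0.0, 60.0)
    reflectance_mean: float = 3.0

    def __post_init__(self):
        if self.length_cm <= 0 or self.width_cm <= 0:
            raise ParameterError("leaf dimensions must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Sensor imperfections, all applied in polar range space.

    range_sigma_cm:
        Gaussian sigma of the range jitter per return.
    outlier_rate:
        Probability that a return is a spurious outlier, displaced
        along the beam by a random offset of 0.5-1.5 x
        ``outlier_magnitude_cm`` with random sign — far enough from the
        surface to be isolated, spread enough that coincident outliers
        are vanishingly rare.
    edge_dropout_deg:
        Beams meeting a surface at grazing incidence — within this
        angle of the surface plane — return nothing, emulating edge
        dropouts.
    reflectance_sigma:
        Gaussian jitter of the per-return reflectance count.
    seed:
        Seed of the single generator behind every random draw.
    """

    range_sigma_cm: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude_cm: float = 15.0
    edge_dropout_deg: float = 0.0
    reflectance_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.range_sigma_cm < 0 or not (0 <= self.outlier_rate <= 1):
            raise ParameterError("invalid noise parameters")
        if self.outlier_magnitude_cm <= 0 or self.edge_dropout_deg < 0:
            raise ParameterError("invalid noise parameters")


def _midline_arc_length(length_cm: float, k: float) -> float:
    """Closed-form arc length of z = k s^2 over s in [-L/2, L/2]."""
    if k == 0.0:
        return length_cm
    a = 2.0 * abs(k)
    s = length_cm / 2.0
    return float(s * np.sqrt(1 + (a * s) ** 2) + np.arcsinh(a * s) / a)


def make_leaf(spec: LeafSpec, n_axial: int = 32, n_lateral: int = 12):
    """Mesh one leaf; returns ``(trimesh.Trimesh, truth)`` with truth a
    dict of length_cm (midline arc length), width_cm (max perpendicular
    chord) and area_cm2 (exact mesh surface area).

    The planform is sampled on ``n_axial`` columns along the midline,
    each with ``n_lateral + 1`` vertices across the local width; the
    two tips collapse to single vertices fanned to their neighbouring
    columns, so no triangle is degenerate.
    """
    if n_axial < 4 or n_lateral < 2:
        raise ParameterError("mesh resolution too coarse")
    L, W, k = spec.length_cm, spec.width_cm, spec.bend_coefficient
    s = np.linspace(-L / 2, L / 2, n_axial + 1)
    halfw = (W / 2) * np.sqrt(np.clip(1 - (2 * s / L) ** 2, 0.0, None))
    z = k * s * s

    verts = [np.array([s[0], 0.0, z[0]])]          # tip 0
    col_start = []                                  # first vertex id per column
    for i in range(1, n_axial):
        col_start.append(len(verts))
        u = np.linspace(-halfw[i], halfw[i], n_lateral + 1)
        for y in u:
            verts.append(np.array([s[i], y, z[i]]))
    tip1 = len(verts)
    verts.append(np.array([s[-1], 0.0, z[-1]]))
    verts = np.asarray(verts)

    faces = []
    first = col_start[0]
    for j in range(n_lateral):                      # fan at tip 0
        faces.append([0, first + j, first + j + 1])
    for a, b in zip(col_start[:-1], col_start[1:]):  # interior quads
        for j in range(n_lateral):
            faces.append([a + j, b + j, b + j + 1])
            faces.append([a + j, b + j + 1, a + j + 1])
    last = col_start[-1]
    for j in range(n_lateral):                      # fan at tip 1
        faces.append([last + j, tip1, last + j + 1])

    # place the leaf: yaw about the depth axis, then translate
    yaw = np.deg2rad(spec.yaw_deg)
    rot = np.array([[np.cos(yaw), -np.sin(yaw), 0.0],
                    [np.sin(yaw), np.cos(yaw), 0.0],
                    [0.0, 0.0, 1.0]])
    verts = verts @ rot.T + np.asarray(spec.center, float)

    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    truth = {
        "length_cm": _midline_arc_length(L, k),
        "width_cm": W,
        "area_cm2": float(mesh.area),
    }
    return mesh, truth


@dataclass
class SyntheticScene:
    """Leaves above a ground plane, viewed by a scanner at
    ``scanner_origin`` looking toward +Z (depth)."""

    leaves: List[LeafSpec]
    ground_z_cm: float = 75.0
    ground_reflectance_mean: float = 50.0
    scanner_origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    plant_id: str = "synthetic"
    mesh_n_axial: int = 32
    mesh_n_lateral: int = 12

    def __post_init__(self):
        self._meshes = None
        self._truths = None

    def _build(self):
        if self._meshes is None:
            built = [make_leaf(s, self.mesh_n_axial, self.mesh_n_lateral)
                     for s in self.leaves]
            self._meshes = [m for m, _ in built]
            self._truths = [t for _, t in built]

    @property
    def meshes(self) -> List[trimesh.Trimesh]:
        self._build()
        return self._meshes

    @property
    def truths(self) -> List[dict]:
        self._build()
        return self._truths

    def leaf_bounds(self) -> np.ndarray:
        """(2, 3) min/max over all leaf mesh vertices."""
        if not self.leaves:
            raise GeometryError("scene has no leaves")
        pts = np.vstack([m.vertices for m in self.meshes])
        return np.vstack([pts.min(axis=0), pts.max(axis=0)])


def scene_ground_truth(scene: SyntheticScene) -> pd.DataFrame:
    """Per-leaf analytic truth table (leaf ids 1..n in scene order)."""
    rows = [
        {"plant_id": scene.plant_id, "leaf_id": i + 1, **t}
        for i, t in enumerate(scene.truths)
    ]
    return pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


# ---------------------------------------------------------------------------
# geometry builders


def rail_geometry_for_scene(
    scene: SyntheticScene,
    rail_speed_cm_s: float = RAIL_SPEED_CM_S,
    scan_frequency_hz: float = SCAN_FREQUENCY_HZ,
    phi_step_deg: float = 0.05,
    margin_cm: float = 1.0,
):
    """Line-rail geometry covering the scene's leaves.

    Returns ``(geometry, n_lines)``: beam angles sweep the lateral
    (Y at depth) extent of the leaves plus a margin; the rail starts at
    the scanner origin and runs past the far leaf edge.
    """
    lo, hi = scene.leaf_bounds()
    ox, oy, oz = scene.scanner_origin
    spacing = rail_speed_cm_s / scan_frequency_hz
    if lo[0] < ox:
        raise GeometryError("scene extends behind the rail start")
    n_lines = int(np.ceil((hi[0] + margin_cm - ox) / spacing)) + 1

    # beam angle phi measured from +Y in the Y-Z plane: phi = atan2(z, y)
    pts = np.vstack([m.vertices for m in scene.meshes])
    phi = np.rad2deg(np.arctan2(pts[:, 2] - oz, pts[:, 1] - oy))
    pad = np.rad2deg(np.arctan2(margin_cm, max(lo[2] - oz, 1.0)))
    lo_phi, hi_phi = phi.min() - pad, phi.max() + pad
    n_cols = int(np.ceil((hi_phi - lo_phi) / phi_step_deg)) + 1
    geom = ScanGeometry(
        mode="line_rail",
        elevation_deg=np.linspace(lo_phi, hi_phi, n_cols),
        rail_speed_cm_s=rail_speed_cm_s,
        scan_frequency_hz=scan_frequency_hz,
    )
    return geom, n_lines


def pan_tilt_geometry_for_scene(
    scene: SyntheticScene,
    azimuth_step_deg: float = 0.5,
    elevation_step_deg: float = 0.5,
    margin_cm: float = 1.0,
) -> ScanGeometry:
    """Pan-tilt geometry covering the scene's leaves at the given servo
    step angles (coarse steps emulate the sparse low-cost head)."""
    pts = np.vstack([m.vertices for m in scene.meshes])
    o = np.asarray(scene.scanner_origin, float)
    rel = pts - o
    r = np.linalg.norm(rel, axis=1)
    phi = np.rad2deg(np.arccos(np.clip(rel[:, 0] / r, -1, 1)))
    theta = np.rad2deg(np.arctan2(rel[:, 2], rel[:, 1]))
    depth = max(scene.leaf_bounds()[0][2] - o[2], 1.0)
    pad = np.rad2deg(np.arctan2(margin_cm, depth))

    def axis(vmin, vmax, step):
        n = int(np.ceil((vmax - vmin) / step)) + 1
        return np.linspace(vmin, vmax, n)

    return ScanGeometry(
        mode="pan_tilt",
        azimuth_deg=axis(phi.min() - pad, phi.max() + pad, azimuth_step_deg),
        elevation_deg=axis(theta.min() - pad, theta.max() + pad,
                           elevation_step_deg),
    )


# ---------------------------------------------------------------------------
# ray casting


def _scene_triangles(scene: SyntheticScene, ground_extent_cm: float = 500.0):
    """All scene triangles + object ids (0 ground, 1..n leaves)."""
    v0s, e1s, e2s, ids = [], [], [], []
    for k, mesh in enumerate(scene.meshes, start=1):
        tri = mesh.triangles
        v0s.append(tri[:, 0])
        e1s.append(tri[:, 1] - tri[:, 0])
        e2s.append(tri[:, 2] - tri[:, 0])
        ids.append(np.full(len(tri), k))
    g = ground_extent_cm
    z = scene.ground_z_cm
    quad = np.array([[-g, -g, z], [g, -g, z], [g, g, z], [-g, g, z]])
    for tri in ([0, 1, 2], [0, 2, 3]):
        v0s.append(quad[tri[0]][None])
        e1s.append((quad[tri[1]] - quad[tri[0]])[None])
        e2s.append((quad[tri[2]] - quad[tri[0]])[None])
        ids.append(np.zeros(1))
    return (np.vstack(v0s), np.vstack(e1s), np.vstack(e2s),
            np.concatenate(ids).astype(int))


def _cast(origins, dirs, v0, e1, e2):
    """Moller-Trumbore: nearest hit distance and triangle per ray.

    origins/dirs are (N, 3); triangles (T, 3).  Returns (t, tri_index)
    with t = inf and index -1 for misses.
    """
    n = origins.shape[0]
    best_t = np.full(n, np.inf)
    best_tri = np.full(n, -1, dtype=np.int64)
    if v0.shape[0] == 0 or n == 0:
        return best_t, best_tri
    h = np.cross(dirs[:, None, :], e2[None, :, :])          # (N, T, 3)
    a = np.einsum("tj,ntj->nt", e1, h)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 / a
        s = origins[:, None, :] - v0[None, :, :]
        u = f * np.einsum("ntj,ntj->nt", s, h)
        q = np.cross(s, e1[None, :, :])
        v = f * np.einsum("ntj,ntj->nt", dirs[:, None, :], q)
        t = f * np.einsum("tj,ntj->nt", e2, q)
    eps = 1e-9
    ok = ((np.abs(a) > eps) & (u >= -eps) & (v >= -eps)
          & (u + v <= 1 + eps) & (t > eps))
    t = np.where(ok, t, np.inf)
    idx = np.argmin(t, axis=1)
    tmin = t[np.arange(n), idx]
    hit = np.isfinite(tmin)
    best_t[hit] = tmin[hit]
    best_tri[hit] = idx[hit]
    return best_t, best_tri


@dataclass
class ScanDiagnostics:
    """Per-cell bookkeeping of a simulated scan: which object each beam
    hit (-1 miss, 0 ground, k = leaf k) and which returns were turned
    into outliers."""

    object_id: np.ndarray
    outlier: np.ndarray


def simulate_scan(
    scene: SyntheticScene,
    geometry: ScanGeometry,
    noise: Optional[NoiseModel] = None,
    n_lines: Optional[int] = None,
    return_diagnostics: bool = False,
):
    """Ray-cast the scene into a polar scan grid.

    One ray per grid cell.  Pan-tilt rays all leave the scanner origin
    with direction ``(cos phi, sin phi cos theta, sin phi sin theta)``
    — the inverse of the Cartesian conversion; line-rail rays leave an
    origin translated ``i * speed / frequency`` along X for scan line
    ``i`` with direction ``(0, cos phi, sin phi)``.  ``n_lines`` sets
    the number of scan lines in line-rail mode.  Range is the distance
    to the nearest surface, then noise is applied in range space;
    missed beams are missing cells.  Fully reproducible from
    ``noise.seed``.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    v0, e1, e2, obj_of_tri = _scene_triangles(scene)
    normals = np.cross(e1, e2)
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-300)
    origin = np.asarray(scene.scanner_origin, float)

    if geometry.mode == "line_rail":
        if n_lines is None or n_lines < 1:
            raise GeometryError("line_rail simulation requires n_lines >= 1")
        n_rows, n_cols = n_lines, geometry.elevation_deg.size
        phi = np.deg2rad(geometry.elevation_deg)
        dirs = np.column_stack([np.zeros_like(phi), np.cos(phi), np.sin(phi)])
        spacing = geometry.line_spacing_cm
        rho = np.full((n_rows, n_cols), np.inf)
        tri_hit = np.full((n_rows, n_cols), -1, dtype=np.int64)
        tri_xmin = np.minimum.reduce([v0[:, 0], (v0 + e1)[:, 0], (v0 + e2)[:, 0]])
        tri_xmax = np.maximum.reduce([v0[:, 0], (v0 + e1)[:, 0], (v0 + e2)[:, 0]])
        for i in range(n_rows):
            # rail rays have no X component: a line at x_i can only hit
            # triangles whose X range covers x_i
            x_i = origin[0] + i * spacing
            cand = np.flatnonzero((tri_xmin <= x_i + 1e-9)
                                  & (tri_xmax >= x_i - 1e-9))
            if cand.size == 0:
                continue
            o = np.broadcast_to(np.array([x_i, origin[1], origin[2]]),
                                (n_cols, 3))
            t, local = _cast(o, dirs, v0[cand], e1[cand], e2[cand])
            rho[i] = t
            hit = local >= 0
            tri_hit[i, hit] = cand[local[hit]]
        ray_dirs = np.broadcast_to(dirs[None, :, :], (n_rows, n_cols, 3))
    else:
        az = np.deg2rad(geometry.azimuth_deg)[:, None]
        el = np.deg2rad(geometry.elevation_deg)[None, :]
        n_rows, n_cols = az.size, el.size
        dx = np.broadcast_to(np.cos(az), (n_rows, n_cols))
        dy = np.sin(az) * np.cos(el)
        dz = np.sin(az) * np.sin(el)
        ray_dirs = np.stack([dx, dy, dz], axis=-1)
        flat_dirs = ray_dirs.reshape(-1, 3)
        rho = np.full(flat_dirs.shape[0], np.inf)
        tri_hit = np.full(flat_dirs.shape[0], -1, dtype=np.int64)
        chunk = 2048
        for a in range(0, flat_dirs.shape[0], chunk):
            b = min(a + chunk, flat_dirs.shape[0])
            o = np.broadcast_to(origin, (b - a, 3))
            rho[a:b], tri_hit[a:b] = _cast(o, flat_dirs[a:b], v0, e1, e2)
        rho = rho.reshape(n_rows, n_cols)
        tri_hit = tri_hit.reshape(n_rows, n_cols)

    hit = np.isfinite(rho)
    obj = np.where(hit, obj_of_tri[tri_hit], -1)

    # grazing-incidence dropout: beam within edge_dropout_deg of the
    # struck surface's plane
    if noise.edge_dropout_deg > 0:
        cosang = np.abs(np.einsum("rcj,rcj->rc", ray_dirs,
                                  normals[tri_hit]))
        grazing = hit & (cosang < np.sin(np.deg2rad(noise.edge_dropout_deg)))
        hit &= ~grazing
        obj[grazing] = -1

    outlier = np.zeros_like(hit)
    if noise.range_sigma_cm > 0:
        rho = rho + rng.normal(0.0, noise.range_sigma_cm, rho.shape)
    if noise.outlier_rate > 0:
        outlier = hit & (rng.random(rho.shape) < noise.outlier_rate)
        mag = noise.outlier_magnitude_cm * rng.uniform(0.5, 1.5, rho.shape)
        sign = np.where(rng.random(rho.shape) < 0.5, -1.0, 1.0)
        rho = np.where(outlier, rho + sign * mag, rho)
    rho = np.where(hit, np.maximum(rho, 0.0), np.nan)

    refl_mean = np.full(rho.shape, np.nan)
    refl_mean[obj == 0] = scene.ground_reflectance_mean
    for k, leaf in enumerate(scene.leaves, start=1):
        refl_mean[obj == k] = leaf.reflectance_mean
    refl = refl_mean
    if noise.reflectance_sigma > 0:
        refl = refl + rng.normal(0.0, noise.reflectance_sigma, rho.shape)
    refl = np.where(hit, np.clip(refl, 0.0, None), np.nan)

    grid = PolarScanGrid(rho, refl, geometry)
    if return_diagnostics:
        return grid, ScanDiagnostics(object_id=obj, outlier=outlier & hit)
    return grid


# ---------------------------------------------------------------------------
# evaluation helpers


def match_segments_to_leaves(
    truth_ids: np.ndarray,
    segments: Sequence[LeafSegment],
    n_leaves: int,
) -> Dict[int, Optional[int]]:
    """Map each ground-truth leaf to the segment that captured it.

    ``truth_ids`` gives, per point of the segmented cloud, the leaf the
    originating beam hit (1..n, 0 for non-leaf).  A leaf counts as
    detected when at least half of its points fall inside one output
    segment; the mapping is leaf id -> segment label (None when
    undetected).
    """
    truth_ids = np.asarray(truth_ids)
    out: Dict[int, Optional[int]] = {}
    for leaf in range(1, n_leaves + 1):
        n_leaf = int(np.sum(truth_ids == leaf))
        out[leaf] = None
        if n_leaf == 0:
            continue
        for seg in segments:
            overlap = int(np.sum(truth_ids[seg.point_indices] == leaf))
            if overlap * 2 >= n_leaf:
                out[leaf] = seg.label
                break
    return out


def count_detected_leaves(truth_ids, segments, n_leaves: int) -> int:
    """Number of ground-truth leaves detected under the half-overlap rule."""
    m = match_segments_to_leaves(truth_ids, segments, n_leaves)
    return sum(1 for v in m.values() if v is not None)


# ---------------------------------------------------------------------------
# the standard validation scene


def demo_scene(bend: float = 0.0) -> SyntheticScene:
    """Three non-overlapping 12 x 6 cm leaves at 60 cm depth over a
    ground plane 15 cm behind them — the standard validation scene."""
    leaves = [
        LeafSpec(12.0, 6.0, bend, yaw_deg=0.0, center=(8.0, -5.0, 60.0)),
        LeafSpec(12.0, 6.0, bend, yaw_deg=0.0, center=(17.0, 5.0, 60.0)),
        LeafSpec(12.0, 6.0, bend, yaw_deg=90.0, center=(26.0, -5.0, 60.0)),
    ]
    return SyntheticScene(leaves=leaves, ground_z_cm=75.0)


# ---------------------------------------------------------------------------
# scene description (de)serialisation


def scene_to_dict(scene: SyntheticScene) -> dict:
    return {
        "plant_id": scene.plant_id,
        "ground_z_cm": scene.ground_z_cm,
        "ground_reflectance_mean": scene.ground_reflectance_mean,
        "scanner_origin": list(scene.scanner_origin),
        "leaves": [
            {
                "length_cm": s.length_cm,
                "width_cm": s.width_cm,
                "bend_coefficient": s.bend_coefficient,
                "yaw_deg": s.yaw_deg,
                "center": list(s.center),
                "reflectance_mean": s.reflectance_mean,
            }
            for s in scene.leaves
        ],
    }


def scene_from_dict(d: dict) -> SyntheticScene:
    known = {"plant_id", "ground_z_cm", "ground_reflectance_mean",
             "scanner_origin", "leaves"}
    unknown = set(d) - known
    if unknown:
        raise ParameterError(f"unknown scene keys: {sorted(unknown)}")
    leaves = [LeafSpec(
        length_cm=l["length_cm"],
        width_cm=l["width_cm"],
        bend_coefficient=l.get("bend_coefficient", 0.0),
        yaw_deg=l.get("yaw_deg", 0.0),
        center=tuple(l.get("center", (0.0, 0.0, 60.0))),
        reflectance_mean=l.get("reflectance_mean", 3.0),
    ) for l in d.get("leaves", [])]
    return SyntheticScene(
        leaves=leaves,
        ground_z_cm=d.get("ground_z_cm", 75.0),
        ground_reflectance_mean=d.get("ground_reflectance_mean", 50.0),
        scanner_origin=tuple(d.get("scanner_origin", (0.0, 0.0, 0.0))),
        plant_id=d.get("plant_id", "synthetic"),
    )
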