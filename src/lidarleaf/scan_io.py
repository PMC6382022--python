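"""File I/O for scan grids, point clouds and ground-truth trait tables.

A scan is stored as two parallel headerless CSV numeric matrices — polar
range in centimetres and reflectance in digital counts — plus a YAML
sidecar describing the scanner geometry.  Dropout cells (no return) are
encoded as an empty field or a ``NaN`` token and survive round trips.

Point clouds travel as whitespace-delimited XYZ text or ASCII PLY with
``x, y, z`` float properties and an optional ``reflectance`` scalar.
Ground truth is a header-bearing CSV with one row per annotated leaf.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, GeometryError
from .geometry import PointCloud, ScanGeometry

__all__ = [
    "PolarScanGrid",
    "read_scan",
    "write_scan",
    "read_pointcloud",
    "write_pointcloud",
    "read_ground_truth",
    "write_ground_truth",
    "GROUND_TRUTH_COLUMNS",
]

GROUND_TRUTH_COLUMNS = ["plant_id", "leaf_id", "length_cm", "width_cm", "area_cm2"]

_MISSING_TOKENS = {"", "nan"}


@dataclass
class PolarScanGrid:
    """Raw scanner output: an R x C polar range matrix (cm), the parallel
    reflectance matrix, and the geometry that maps cells to directions.

    Missing cells (LiDAR dropouts) are NaN in both matrices.  Present
    range values must be finite and non-negative; the grid shape must be
    consistent with the geometry (rows = vertical steps or scan lines,
    columns = horizontal steps or beam angles).
    """

    range_cm: np.ndarray
    reflectance: Optional[np.ndarray]
    geometry: ScanGeometry
    timestamp: str = ""

    def __post_init__(self):
        self.range_cm = np.atleast_2d(np.asarray(self.range_cm, dtype=float))
        if self.reflectance is not None:
            self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
            if self.reflectance.shape != self.range_cm.shape:
                raise FormatError(
                    f"range matrix {self.range_cm.shape} and reflectance matrix "
                    f"{self.reflectance.shape} have different shapes"
                )
        r, c = self.range_cm.shape
        if r < 1 or c < 1:
            raise FormatError("scan grid must have at least one row and column")
        present = np.isfinite(self.range_cm)
        if np.any(self.range_cm[present] < 0):
            raise FormatError("range values must be non-negative")
        if c != self.geometry.expected_columns():
            raise GeometryError(
                f"grid has {c} columns but geometry defines "
                f"{self.geometry.expected_columns()} beam angles"
            )
        er = self.geometry.expected_rows()
        if er is not None and r != er:
            raise GeometryError(
                f"grid has {r} rows but geometry defines {er} vertical steps"
            )

    @property
    def shape(self):
        return self.range_cm.shape


def _parse_matrix_csv(path: Union[str, Path]) -> np.ndarray:
    """Parse a headerless numeric CSV; empty/NaN tokens become NaN.
    Non-numeric cells raise a FormatError naming the 1-based row and
    column, and ragged rows raise too — rows are never silently dropped."""
    rows = []
    width = None
    with open(path, "r") as fh:
        for r, line in enumerate(fh):
            line = line.rstrip("\n").rstrip("\r")
            if line == "" and width is None:
                continue  # leading blank line
            tokens = line.split(",")
            if width is None:
                width = len(tokens)
            elif len(tokens) != width:
                raise FormatError(
                    f"{path}: row {r + 1} has {len(tokens)} fields, expected {width}"
                )
            vals = np.empty(len(tokens))
            for c, tok in enumerate(tokens):
                t = tok.strip()
                if t.lower() in _MISSING_TOKENS:
                    vals[c] = np.nan
                else:
                    try:
                        vals[c] = float(t)
                    except ValueError:
                        raise FormatError(
                            f"{path}: non-numeric cell {t!r} at row {r + 1}, "
                            f"column {c + 1}"
                        ) from None
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: empty matrix")
    return np.vstack(rows)


def _geometry_to_dict(g: ScanGeometry) -> dict:
    d = {"mode": g.mode, "elevation_deg": [float(v) for v in g.elevation_deg]}
    if g.azimuth_deg is not None:
        d["azimuth_deg"] = [float(v) for v in g.azimuth_deg]
    if g.rail_speed_cm_s is not None:
        d["rail_speed_cm_s"] = float(g.rail_speed_cm_s)
    if g.scan_frequency_hz is not None:
        d["scan_frequency_hz"] = float(g.scan_frequency_hz)
    return d


def _geometry_from_dict(d: dict) -> ScanGeometry:
    known = {"mode", "elevation_deg", "azimuth_deg", "rail_speed_cm_s",
             "scan_frequency_hz"}
    unknown = set(d) - known
    if unknown:
        raise FormatError(f"unknown geometry metadata keys: {sorted(unknown)}")
    try:
        return ScanGeometry(
            mode=d["mode"],
            elevation_deg=np.asarray(d["elevation_deg"], float),
            azimuth_deg=(np.asarray(d["azimuth_deg"], float)
                         if "azimuth_deg" in d else None),
            rail_speed_cm_s=d.get("rail_speed_cm_s"),
            scan_frequency_hz=d.get("scan_frequency_hz"),
        )
    except KeyError as e:
        raise FormatError(f"scan metadata missing required key: {e}") from None


def read_scan(range_path, reflectance_path, metadata_path) -> PolarScanGrid:
    """Load a scan from its range CSV, reflectance CSV and YAML sidecar.

    The two matrices must have identical shapes; a mismatch raises a
    :class:`FormatError` naming both shapes.
    """
    rng = _parse_matrix_csv(range_path)
    refl = _parse_matrix_csv(reflectance_path)
    if rng.shape != refl.shape:
        raise FormatError(
            f"range matrix is {rng.shape} but reflectance matrix is {refl.shape}"
        )
    with open(metadata_path, "r") as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "geometry" not in meta:
        raise FormatError(f"{metadata_path}: metadata must contain a 'geometry' record")
    geom = _geometry_from_dict(meta["geometry"])
    return PolarScanGrid(rng, refl, geom, timestamp=str(meta.get("timestamp", "")))


def write_scan(grid: PolarScanGrid, range_path, reflectance_path, metadata_path,
               fmt: str = "%.9g") -> None:
    """Write a scan as the CSV pair + YAML sidecar read by :func:`read_scan`.
    Missing cells are written as empty fields."""
    for mat, path in ((grid.range_cm, range_path),
                      (grid.reflectance, reflectance_path)):
        if mat is None:
            mat = np.full_like(grid.range_cm, np.nan)
        with open(path, "w") as fh:
            for row in mat:
                fh.write(",".join("" if not np.isfinite(v) else fmt % v
                                  for v in row) + "\n")
    meta = {
        "timestamp": grid.timestamp or _dt.datetime.now().strftime("%Y%m%d-%H%M%S"),
        "geometry": _geometry_to_dict(grid.geometry),
    }
    with open(metadata_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# point clouds


def write_pointcloud(cloud: PointCloud, path, format: Optional[str] = None) -> None:
    """Serialise a cloud as whitespace XYZ text or ASCII PLY.

    Format is taken from the extension when not given.  Coordinates are
    written in centimetres with 9 significant digits; reflectance, when
    present, becomes a fourth column (XYZ) or a scalar vertex property
    (PLY).
    """
    path = Path(path)
    if format is None:
        format = "ply" if path.suffix.lower() == ".ply" else "xyz"
    if format not in ("xyz", "ply"):
        raise ValueError(f"unknown point-cloud format {format!r}")
    has_r = cloud.reflectance is not None
    with open(path, "w") as fh:
        if format == "ply":
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(cloud)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            if has_r:
                fh.write("property float reflectance\n")
            fh.write("end_header\n")
        for i in range(len(cloud)):
            cols = [f"{cloud.x_cm[i]:.9g}", f"{cloud.y_cm[i]:.9g}",
                    f"{cloud.z_cm[i]:.9g}"]
            if has_r:
                cols.append(f"{cloud.reflectance[i]:.9g}")
            fh.write(" ".join(cols) + "\n")


def _read_ply(path) -> PointCloud:
    with open(path, "r") as fh:
        magic = fh.readline().strip()
        if magic != "ply":
            raise FormatError(f"{path}: not a PLY file (missing 'ply' magic)")
        n_vertex = None
        props = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: unterminated PLY header")
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "format":
                if tok[1] != "ascii":
                    raise FormatError(f"{path}: only ASCII PLY is supported")
            elif tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tok[2])
            elif tok[0] == "property" and in_vertex:
                props.append(tok[-1])
            elif tok[0] == "end_header":
                break
        if n_vertex is None:
            raise FormatError(f"{path}: PLY header has no vertex element")
        for need in ("x", "y", "z"):
            if need not in props:
                raise FormatError(f"{path}: vertex element lacks property {need!r}")
        if n_vertex == 0:
            data = np.empty((0, len(props)))
        else:
            data = np.loadtxt(fh, dtype=float, ndmin=2, max_rows=n_vertex)
        if data.shape[0] != n_vertex:
            raise FormatError(
                f"{path}: header declares {n_vertex} vertices, found {data.shape[0]}"
            )
    ix, iy, iz = props.index("x"), props.index("y"), props.index("z")
    refl = data[:, props.index("reflectance")] if "reflectance" in props else None
    return PointCloud(data[:, ix], data[:, iy], data[:, iz], refl)


def read_pointcloud(path) -> PointCloud:
    """Read a cloud written by :func:`write_pointcloud`; point order is
    preserved."""
    path = Path(path)
    with open(path, "r") as fh:
        first = fh.readline().strip()
    if first == "ply":
        return _read_ply(path)
    with open(path) as fh:
        if not fh.read().strip():
            return PointCloud(np.empty(0), np.empty(0), np.empty(0))
    data = np.loadtxt(path, dtype=float, ndmin=2)
    if data.shape[1] not in (3, 4):
        raise FormatError(f"{path}: XYZ rows must have 3 or 4 columns")
    refl = data[:, 3] if data.shape[1] == 4 else None
    return PointCloud(data[:, 0], data[:, 1], data[:, 2], refl)


# ---------------------------------------------------------------------------
# ground-truth trait tables


def read_ground_truth(path) -> pd.DataFrame:
    """Read a per-leaf ground-truth trait table.

    Columns: plant_id, leaf_id, length_cm, width_cm, area_cm2.
    (plant_id, leaf_id) must be unique and trait values positive.
    """
    df = pd.read_csv(path)
    missing = [c for c in GROUND_TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: ground-truth table lacks columns {missing}")
    df = df[GROUND_TRUTH_COLUMNS].copy()
    df["plant_id"] = df["plant_id"].astype(str)
    df["leaf_id"] = df["leaf_id"].astype(int)
    if df.duplicated(["plant_id", "leaf_id"]).any():
        raise FormatError(f"{path}: duplicate (plant_id, leaf_id) rows")
    traits = df[["length_cm", "width_cm", "area_cm2"]].to_numpy(float)
    if not np.all(traits > 0):
        raise FormatError(f"{path}: all trait values must be positive")
    return df


def write_ground_truth(df: pd.DataFrame, path) -> None:
    df[GROUND_TRUTH_COLUMNS].to_csv(path, index=False)
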