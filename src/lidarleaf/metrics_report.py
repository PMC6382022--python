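"""Accuracy assessment and the per-leaf trait report.

Estimates are scored against manual ground truth with three standard
statistics: the absolute percentage error of each leaf,

    APE = |actual - estimated| / actual * 100,

the root-mean-square error over all compared leaves,

    RMSE = sqrt( sum_i (truth_i - estimate_i)^2 / n ),

and the coefficient of determination r^2 — here the squared Pearson
correlation of truth and estimate, the value a least-squares regression
scatter plot reports.  Detection is scored separately as the
segmentation rate (detected / annotated leaves), so an undetected leaf
lowers the rate but never enters the error statistics.

Ground-truth leaf areas from flatbed document scans convert from pixel
counts through the per-pixel area: at ``dpi`` dots per inch each pixel
covers ``(25400 / dpi)^2`` square micrometres (25 400 um to the inch) —
7168.44 um^2 at the 300 dpi used for leaf scanning.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .segmentation import segmentation_rate

__all__ = [
    "ape",
    "rmse",
    "r_squared",
    "pixel_area_um2",
    "area_from_pixel_count_cm2",
    "make_comparison",
    "build_report",
    "TRAIT_NAMES",
]

TRAIT_NAMES = ("length", "width", "area")

_UM_PER_INCH = 25400.0


def ape(actual: float, estimated: float) -> float:
    """Absolute percentage error of one estimate."""
    if actual == 0:
        raise ValueError("APE is undefined for a zero actual value")
    return abs(actual - estimated) / abs(actual) * 100.0


def rmse(truth, estimate) -> float:
    """Root-mean-square error of paired vectors (missing pairs must be
    excluded beforehand)."""
    t = np.asarray(truth, float).ravel()
    e = np.asarray(estimate, float).ravel()
    if t.size != e.size or t.size == 0:
        raise ValueError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((t - e) ** 2)))


def r_squared(truth, estimate) -> float:
    """Squared Pearson correlation of truth and estimate."""
    t = np.asarray(truth, float).ravel()
    e = np.asarray(estimate, float).ravel()
    if t.size != e.size or t.size < 2:
        raise ValueError("r_squared needs two equal-length vectors of size >= 2")
    if np.ptp(t) == 0:
        raise ValueError("r_squared is undefined for constant truth")
    return float(np.corrcoef(t, e)[0, 1] ** 2)


def pixel_area_um2(dpi: float = 300.0) -> float:
    """Area of one scanner pixel in square micrometres at ``dpi``."""
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    return (_UM_PER_INCH / dpi) ** 2


def area_from_pixel_count_cm2(n_pixels: int, dpi: float = 300.0) -> float:
    """Leaf area (cm^2) from the count of leaf-coloured pixels in a
    flatbed scan."""
    return n_pixels * pixel_area_um2(dpi) * 1e-8  # um^2 -> cm^2


def make_comparison(
    ground_truth: pd.DataFrame,
    estimates: pd.DataFrame,
) -> pd.DataFrame:
    """Join ground truth with estimates into the long comparison table.

    ``ground_truth`` has columns plant_id, leaf_id, length_cm, width_cm,
    area_cm2; ``estimates`` the same (NaN or absent rows for undetected
    leaves).  Output rows: (plant_id, leaf_id, trait, actual, estimated)
    with estimated NaN for undetected leaves.
    """
    est = estimates.set_index(["plant_id", "leaf_id"]) if len(estimates) else None
    rows = []
    for _, gt in ground_truth.iterrows():
        key = (gt["plant_id"], gt["leaf_id"])
        for trait in TRAIT_NAMES:
            col = f"{trait}_cm" if trait != "area" else "area_cm2"
            estimated = np.nan
            if est is not None and key in est.index:
                estimated = float(est.loc[key, col])
            rows.append({
                "plant_id": gt["plant_id"],
                "leaf_id": int(gt["leaf_id"]),
                "trait": trait,
                "actual": float(gt[col]),
                "estimated": estimated,
            })
    return pd.DataFrame(rows, columns=["plant_id", "leaf_id", "trait",
                                       "actual", "estimated"])


def build_report(
    comparisons: pd.DataFrame,
    n_annotated: Mapping[str, int],
    path=None,
) -> pd.DataFrame:
    """Assemble the accuracy report and optionally write it as CSV.

    Three sections in one table, marked by the ``section`` column:

    ``leaf``
        one row per comparison row, with its APE (NaN if undetected);
    ``plant``
        per (plant, trait) minimum/mean/maximum APE over detected
        leaves, plus the plant's segmentation rate;
    ``overall``
        per-trait RMSE and r^2 over every detected leaf of every plant.

    A leaf counts as detected when at least one of its trait estimates
    is present.
    """
    df = comparisons.copy()
    with np.errstate(invalid="ignore"):
        df["ape_percent"] = (df["actual"] - df["estimated"]).abs() / df["actual"] * 100
    df.insert(0, "section", "leaf")

    plant_rows = []
    for plant, g in df.groupby("plant_id", sort=False):
        detected = (
            g.dropna(subset=["estimated"])
            .groupby("leaf_id").size().index.size
        )
        rate = segmentation_rate(detected, int(n_annotated[plant]))
        for trait in TRAIT_NAMES:
            apes = g.loc[g["trait"] == trait, "ape_percent"].dropna()
            plant_rows.append({
                "section": "plant", "plant_id": plant, "trait": trait,
                "min_ape": apes.min() if len(apes) else np.nan,
                "mean_ape": apes.mean() if len(apes) else np.nan,
                "max_ape": apes.max() if len(apes) else np.nan,
                "segmentation_rate": rate,
            })

    overall_rows = []
    for trait in TRAIT_NAMES:
        g = df[(df["trait"] == trait)].dropna(subset=["estimated"])
        row = {"section": "overall", "trait": trait}
        if len(g):
            row["rmse"] = rmse(g["actual"], g["estimated"])
            row["r_squared"] = (r_squared(g["actual"], g["estimated"])
                                if len(g) >= 2 and np.ptp(g["actual"]) > 0
                                else np.nan)
        else:
            row["rmse"] = np.nan
            row["r_squared"] = np.nan
        overall_rows.append(row)

    report = pd.concat(
        [df, pd.DataFrame(plant_rows), pd.DataFrame(overall_rows)],
        ignore_index=True,
    )
    if path is not None:
        report.to_csv(path, index=False, float_format="%.6g")
    return report
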