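# lidarleaf

Per-leaf morphometrics from low-cost LiDAR scans of single plants.

Plant phenotyping needs leaf length, width and surface area without
destructive harvesting. A cheap scanning LiDAR — a single-beam
rangefinder on a pan-tilt head, or a 2-D line scanner carried along a
rail — delivers a polar range grid of the plant from above. `lidarleaf`
is the post-processing side of such a system: it turns raw scan grids
into per-leaf trait estimates and accuracy reports, and ships a virtual
scanner so the whole chain can be exercised and validated without any
hardware.

## The processing chain

1. **Ingestion** (`scan_io`) — paired headerless CSV matrices (polar
   range in cm, reflectance in digital counts) plus a YAML geometry
   sidecar; dropout cells survive round trips as missing values.
2. **Cartesian conversion** (`geometry`) — pan-tilt:
   `X = ρ·cos φ`, `Y = ρ·sin φ·cos θ`, `Z = ρ·sin φ·sin θ`;
   line-rail: `X = i·v/f` (rail position of scan line *i*),
   `Y = ρ·cos φ`, `Z = ρ·sin φ`.
3. **Cleaning** (`preprocess`) — background removal by reflectance
   (vegetation returns low counts; threshold 20) and depth, then a
   neighborhood filter: a point with at least `min_neighbors` others in
   a `(dx, dy, dz)` box around it keeps its position with height
   replaced by the neighbor mean; anything else is an outlier and is
   discarded. Two passes by default.
4. **Segmentation** (`segmentation`) — region growing over
   Euclidean-radius connectivity, accelerated by an octree whose radius
   queries are exactly brute force; each connected component above a
   minimum size is one leaf.
5. **Traits** (`traits`) — length: quadratic midline fit
   `y = a·x² + b·x + c` along the dominant planimetric axis, sampled at
   50 points snapped to real cloud points, summed as 3-D polyline arc
   length (width: the same with axes swapped); area: Delaunay
   triangulation of the planimetric projection with each triangle's
   area `½·√(D₁² + D₂² + D₃²)` evaluated on the 3-D vertices and
   summed.
6. **Accuracy** (`metrics_report`) — per-leaf
   `APE = |actual − estimated|/actual·100`, overall
   `RMSE = √(Σ(tᵢ − eᵢ)²/n)` and r², per-plant min/mean/max APE and
   segmentation rate (detected/annotated leaves).
7. **Virtual scanner** (`synthetic`) — elliptical mesh leaves with
   optional quadratic bend over a high-reflectance ground plane,
   ray-cast in either scanner geometry with seeded range noise, outlier
   returns and grazing dropouts; ground truth (midline arc length, max
   chord width, exact mesh area) is analytic.

## Worked example

```python
from lidarleaf import PipelineConfig, run_all
from lidarleaf.synthetic import demo_scene

result = run_all(demo_scene(), PipelineConfig(range_sigma_cm=0.2,
                                              outlier_rate=0.02,
                                              reflectance_sigma=1.0, seed=7))
report = result["report"]
print(report[report.section == "plant"]
      [["trait", "mean_ape", "max_ape", "segmentation_rate"]])
```

prints

```
     trait  mean_ape   max_ape  segmentation_rate
9   length  0.095635  0.142543                1.0
10   width  0.414774  0.599986                1.0
11    area  0.192208  0.217480                1.0
```

i.e. on the standard three-leaf validation scene scanned with 0.2 cm
range noise and 2% outlier returns, every leaf is detected
(segmentation rate 1.0) and every trait of every leaf is recovered
within 0.6% of the analytic truth. The same chain is available from the
shell — `lidarleaf run-all --seed 7 --out report.csv`, or stage by
stage via the `simulate`, `convert`, `preprocess`, `segment`, `traits`
and `report` subcommands.

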