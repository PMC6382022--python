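# Methods

## Scope and coordinate conventions

All coordinates are centimetres in the scanner frame: the scanner sits
at the origin, X runs along the rail (or the pan axis), Y is the
lateral sweep direction and Z is depth along the dominant viewing
direction. For a top-down scan, "height" in the filtering sense is the
Z (depth) coordinate, and the planimetric plane — the plane in which
leaf planforms live and in which the midline fit and the Delaunay
projection operate — is (X, Y).

A note on the pan-tilt conversion: with azimuth φ (vertical) and
elevation θ (horizontal), the Cartesian mapping is
`X = ρ cos φ, Y = ρ sin φ cos θ, Z = ρ sin φ sin θ`. Writing the second
angular factor as φ rather than θ (an easy transcription slip, since
both Y and Z carry a `sin φ` factor) would collapse the horizontal
sweep onto one vertical plane; the implementation and its round-trip
tests use θ, consistent with the definition of the two sweep angles.
For the line-rail geometry, scan line *i* (0-based) sits at exactly
`i · v/f` so the first line is at 0 cm; at the reference kinematics of
18.0724 cm/s and 360 scans/s this spacing is 0.0502 cm ≈ 0.5 mm. The
beam angle φ is measured in the Y–Z plane from the +Y axis.

## Cleaning model

Background removal uses two cheap cues. Vegetation returns low
reflectance counts (about 5), while pots, tables and soil return much
higher values; the default threshold keeps returns at or below 20
counts, which separates plant from background more reliably than a
vegetation-tight cut of 5. The optional depth cut removes returns at or
beyond a ground-axis coordinate, for scenes where the backdrop shares
the plant's reflectance.

The neighborhood filter plays two roles at once. For each point, the
other points inside an axis-aligned box of full side lengths
`(dx, dy, dz)` centred on it (boundary inclusive, self excluded) are
counted against the *input* cloud of the pass. A point with at least
`min_neighbors` of them survives with its height (z) replaced by the
neighbours' mean height — local smoothing — while points below the
count are isolated returns and are discarded — outlier removal.
Design choices that were genuinely open and how they were fixed:

- *Simultaneous update.* Counts and means never see the pass's own
  edits, so the result is independent of point order; this is also what
  makes an exact O(N²) reference implementation feasible, and the two
  are asserted equal on random clouds.
- *Height-only refinement.* Only z is averaged; x and y are identity.
  Averaging the full centroid would shrink leaf boundaries inward.
- *Count convention.* "At least `min_neighbors`" (≥, not >). The
  off-by-one is immaterial in dense scans but is documented here
  because both readings of a verbal threshold are defensible.
- *Defaults.* Window 1×1×1 cm and `min_neighbors = 4` suit
  centimetre-scale leaves at millimetre scan density; they are starting
  points, not protocol constants — coarser scans need larger windows.
  Two passes are the protocol default.

## Segmentation model

The growth predicate is Euclidean-radius connectivity: two points
belong to the same leaf iff they are linked by a chain of
within-radius steps. This is the weakest predicate consistent with
region growing over spatial neighborhoods; it needs no surface normals
(unreliable at this noise level) and makes the output exactly the
connected components of the radius graph — which is what the test
oracle computes independently via a sparse-graph component search.
Seeds are chosen automatically as the lowest-index unvisited point, so
labels are deterministic; as a partition the result is independent of
point order. The octree accelerator is contractually exact: its radius
queries return the brute-force result set, asserted on random clouds
and across leaf capacities. Components below `min_segment_size`
(default 30 points) are residue — stray returns and partially seen
leaves — and are reported separately rather than labelled.

The default radius of 0.5 cm connects millimetre-spaced returns on one
leaf while keeping leaves a few centimetres apart in separate
components; like the filter window it must be rescaled for sparser
scans.

## Trait estimators

**Length and width.** The dominant planimetric axis is the one with
the larger extent (ties to X). A degree-2 polynomial of the secondary
coordinate against the dominant one captures the curved midline; 50
equally spaced samples spanning the extent *inclusive of both
endpoints* (so the polyline reaches the tips) are snapped to the
nearest actual segment point in the planimetric plane — 2-D distance,
so out-of-plane noise cannot hijack the snapping — and consecutive
duplicates collapse. The trait is the 3-D arc length of this polyline,
which follows the leaf through its bend. Width repeats the procedure
with the axes swapped.

Known limitation: the axis swap measures the width profile along the
secondary *world* axis. For leaves yawed far from axis alignment the
secondary-axis extent is not the anatomical width, and the width
estimate inflates accordingly (a 20° yaw on a 2:1 ellipse already
biases width by tens of percent). Length, area and segmentation are
unaffected by yaw. The validation scene therefore uses axis-aligned
leaves; for field use, rotating each segment to its principal axes
before the width pass would remove the bias but is deliberately not
done here, to keep the estimator the plain axis-swap procedure.

**Area.** Delaunay triangulation of the (X, Y) projection, with each
triangle's area evaluated on the original 3-D vertices via the
determinant form `½√(D₁² + D₂² + D₃²)` (equal to the cross-product
half-magnitude, and tested against it), then summed. Triangulating the
projection and lifting to 3-D is the only reading that yields a
surface from a triangle sum; it matches the top-down scan geometry,
and for planar segments it is exact (a flat 4×5 cm rectangle returns
20.00 cm², tilted or not). Because a projected Delaunay triangulation
fills concavities of non-convex planforms (a convex-hull bias), an
optional long-edge prune (`prune_edge_cm`, 3-D edge lengths) drops
bridging triangles; it is off by default — faithful to the plain
triangle sum — and recommended for lobed leaves. Pruning can only
decrease the estimate, asserted as a property.

Degenerate segments (under 3 points, zero extent, collinear
projections) raise typed errors; the composed `extract_traits` converts
them to per-trait missing values with a warning so one bad segment
cannot abort a scan.

## Virtual scanner and study conditions

The generator emulates what the physical systems produce — polar range
+ reflectance grids — not the systems themselves. Leaves are elliptical
planforms (length = major extent, width = minor) with an optional
quadratic sag `z = k·s²` along the midline, meshed with collapsed tip
fans so no triangle is degenerate, yawed and placed in the scene over a
single high-reflectance ground plane. Ground truth is analytic: length
is the closed-form arc length of the bent midline, width the maximal
perpendicular chord (the planform minor axis), area the exact summed
triangle area of the very mesh the rays hit. The elliptical-with-bend
family is the minimal shape set that exercises every stage (curved
midline for the quadratic fit, 3-D area exceeding projected area);
lobed or serrated planforms, petioles, stems, occlusion and
multi-bounce returns are *not* modelled, so passing recovery tests
bounds algorithmic error, not performance on real canopies.

Noise lives in range (polar) space, where sensor noise physically
arises: Gaussian jitter (`range_sigma_cm`), spurious outlier returns,
grazing-incidence dropouts, reflectance jitter — all from one seeded
generator, so a seed reproduces a grid bit for bit. Outlier returns
are displaced along the beam by `sign · U(0.5, 1.5) · magnitude`
(default magnitude 15 cm) rather than a fixed offset: real spurious
returns land at uncorrelated ranges, and the spread keeps two nearby
outliers from co-locating within the filter window and validating each
other, which a fixed offset at percent-level rates would permit.

The standard validation scene is three non-overlapping flat 12×6 cm
leaves (axis-aligned, yaws 0°/0°/90° — see the width limitation above)
at 60 cm depth over a ground plane at 75 cm, plant reflectance 3
counts against ground 50, scanned by the dense line-rail geometry at
the reference kinematics with 0.05° beam steps (~0.05 × 0.05 cm point
spacing, ~6 × 10⁴ plant points). The two study conditions are the
noiseless scan and a noisy scan with 0.2 cm range sigma, 2% outliers
and unit reflectance jitter. Under these conditions the pipeline
detects 3/3 leaves and recovers all traits within 2% (noiseless) and
well within 10% (noisy), with every injected outlier removed; the
test suite and `scripts/acceptance.py` recompute these end to end.

## Numerical choices

- The midline fit centres the abscissa before `polyfit` for
  conditioning and re-expands the coefficients exactly.
- The box search runs as an inf-norm KD-tree query on window-normalised
  coordinates with a 1 + 1e-12 radius factor to keep boundary pairs
  despite division round-off.
- The octree uses cubic nodes, halts subdivision at capacity or depth
  48 (coincident points), and sorts query results for determinism.
- Ray–triangle intersection is vectorised Möller–Trumbore with a 1e-9
  parallel/self-hit epsilon; line-rail rays carry no X component, so
  each scan line tests only triangles whose X interval covers it.
- Scan CSVs serialise at 9 significant digits; round-trip error is
  below 1e-6 cm and asserted.

## Accuracy report

APE is computed per detected leaf and trait; undetected leaves appear
with missing estimates and enter only the segmentation rate
(detected/annotated, deliberately uncapped so over-segmentation is
visible as a rate above 1). RMSE and r² (squared Pearson correlation,
the convention of regression scatter plots) are computed over detected
leaves across plants. The report is one CSV with `leaf`, `plant` and
`overall` sections, so summaries are always recomputable from the
per-leaf rows they summarise — a consistency the tests assert.
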