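import numpy as np
import pytest
from scipy.integrate import quad

from lidarleaf.errors import DegenerateSegmentError
from lidarleaf.geometry import PointCloud
from lidarleaf.traits import (dominant_axis, extract_traits, fit_midline,
                              leaf_area, leaf_length, leaf_width,
                              midline_polyline)


def grid_cloud(xmax, ymax, step=0.1, z_fn=None):
    gx, gy = np.meshgrid(np.arange(0, xmax + step / 2, step),
                         np.arange(0, ymax + step / 2, step))
    x, y = gx.ravel(), gy.ravel()
    z = np.zeros_like(x) if z_fn is None else z_fn(x, y)
    return PointCloud(x, y, z)


def ellipse_cloud(length, width, step=0.1):
    a, b = length / 2, width / 2
    gx, gy = np.meshgrid(np.arange(-a, a + step / 2, step),
                         np.arange(-b, b + step / 2, step))
    inside = (gx / a) ** 2 + (gy / b) ** 2 <= 1.0
    return PointCloud(gx[inside], gy[inside], np.zeros(inside.sum()))


class TestDominantAxis:
    def test_cases(self):
        strip_x = grid_cloud(10, 2)
        strip_y = grid_cloud(2, 10)
        square = grid_cloud(5, 5)
        assert dominant_axis(strip_x) == "x"
        assert dominant_axis(strip_y) == "y"
        assert dominant_axis(square) == "x"  # tie breaks to x

    def test_degenerate(self):
        with pytest.raises(DegenerateSegmentError):
            dominant_axis(PointCloud([0], [0], [0]))


class TestFitMidline:
    def test_exact_quadratic_recovered(self):
        x = np.linspace(-3, 3, 40)
        y = 2 * x ** 2 + 3 * x + 1
        fit = fit_midline(PointCloud(x, y, np.zeros_like(x)), "x")
        assert (fit.a, fit.b, fit.c) == pytest.approx((2, 3, 1), abs=1e-9)

    def test_constant_line(self):
        x = np.linspace(0, 10, 20)
        fit = fit_midline(PointCloud(x, np.full_like(x, 5.0), x * 0), "x")
        assert (fit.a, fit.b, fit.c) == pytest.approx((0, 0, 5), abs=1e-9)

    def test_noisy_quadratic_within_standard_errors(self, rng):
        n, sigma = 200, 0.05
        x = rng.uniform(-5, 5, n)
        y = 0.3 * x ** 2 - 1.2 * x + 4 + rng.normal(0, sigma, n)
        fit = fit_midline(PointCloud(x, y, x * 0), "x")
        # normal-equations oracle with coefficient standard errors
        A = np.column_stack([x ** 2, x, np.ones(n)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        cov = sigma ** 2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        np.testing.assert_allclose((fit.a, fit.b, fit.c), coef, atol=1e-9)
        assert np.all(np.abs(coef - [0.3, -1.2, 4.0]) < 3 * se + 1e-12)


class TestMidlinePolyline:
    def test_flat_strip_spans_extremes(self):
        cloud = grid_cloud(10, 1, step=0.1)
        fit = fit_midline(cloud, "x")
        poly = midline_polyline(cloud, fit)
        assert poly[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert poly[-1, 0] == pytest.approx(10.0, abs=1e-9)

    def test_two_sample_polyline(self):
        cloud = grid_cloud(10, 1, step=0.5)
        fit = fit_midline(cloud, "x", sample_count=2)
        poly = midline_polyline(cloud, fit)
        assert poly.shape[0] == 2

    def test_vertices_are_segment_members(self, rng):
        x = rng.uniform(0, 10, 500)
        y = 0.05 * x ** 2 + rng.normal(0, 0.3, 500)
        cloud = PointCloud(x, y, rng.normal(0, 0.1, 500))
        poly = midline_polyline(cloud, fit_midline(cloud, "x"))
        xyz = cloud.xyz
        for v in poly:
            assert np.min(np.linalg.norm(xyz - v, axis=1)) < 1e-12


class TestLeafLength:
    def test_flat_strip(self):
        assert leaf_length(grid_cloud(10, 1, step=0.05)) == pytest.approx(
            10.0, rel=0.02)

    def test_three_four_five(self):
        # two-point polyline (0,0,0) -> (3,4,0)
        cloud = PointCloud([0, 1.5, 3], [0, 2, 4], [0, 0, 0])
        fit = fit_midline(cloud, "x", sample_count=2)
        poly = midline_polyline(cloud, fit)
        assert np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)) == \
            pytest.approx(5.0, abs=1e-9)

    def test_bent_leaf_matches_quadrature_arc_length(self):
        # strip bent out of plane: z = 0.05 x^2 over x in [0, 10]
        cloud = grid_cloud(10, 1, step=0.05,
                           z_fn=lambda x, y: 0.05 * x ** 2)
        arc, _ = quad(lambda x: np.sqrt(1 + (0.1 * x) ** 2), 0, 10)
        assert leaf_length(cloud) == pytest.approx(arc, rel=0.03)


class TestLeafWidth:
    def test_flat_rectangle(self):
        assert leaf_width(grid_cloud(10, 4, step=0.05)) == pytest.approx(
            4.0, rel=0.02)

    def test_square_width_equals_length(self):
        square = grid_cloud(6, 6, step=0.05)
        assert leaf_width(square) == pytest.approx(leaf_length(square),
                                                   rel=0.01)

    def test_ellipse_width(self):
        assert leaf_width(ellipse_cloud(10, 4, step=0.05)) == pytest.approx(
            4.0, rel=0.05)


class TestLeafArea:
    def test_flat_rectangle_exact(self):
        assert leaf_area(grid_cloud(4, 5, step=0.1)) == pytest.approx(
            20.0, rel=0.005)

    def test_tilted_rectangle(self):
        # rigid tilt 60 degrees about the X axis
        cloud = grid_cloud(4, 5, step=0.1)
        c, s = np.cos(np.pi / 3), np.sin(np.pi / 3)
        y = cloud.y_cm * c
        z = cloud.y_cm * s
        assert leaf_area(PointCloud(cloud.x_cm, y, z)) == pytest.approx(
            20.0, rel=0.01)

    def test_convex_planar_equals_hull_area(self, rng):
        from scipy.spatial import ConvexHull
        cloud = ellipse_cloud(8, 5, step=0.1)
        hull = ConvexHull(np.column_stack([cloud.x_cm, cloud.y_cm]))
        assert leaf_area(cloud) == pytest.approx(hull.volume, rel=0.005)

    def test_pruning_is_monotone(self, rng):
        cloud = PointCloud.from_xyz(rng.uniform(0, 10, size=(300, 3)))
        full = leaf_area(cloud)
        pruned = leaf_area(cloud, prune_edge_cm=1.0)
        assert pruned <= full + 1e-12

    def test_curved_leaf_matches_mesh_truth(self):
        from lidarleaf.synthetic import LeafSpec, make_leaf
        spec = LeafSpec(10.0, 4.0, bend_coefficient=0.05,
                        center=(0.0, 0.0, 0.0))
        mesh, truth = make_leaf(spec, n_axial=64, n_lateral=24)
        # sample the mesh surface on a planimetric grid
        step = 0.1
        gx, gy = np.meshgrid(np.arange(-5, 5, step), np.arange(-2, 2, step))
        a, b = 5.0, 2.0
        inside = (gx / a) ** 2 + (gy / b) ** 2 <= 0.999
        x, y = gx[inside], gy[inside]
        z = 0.05 * x ** 2
        assert leaf_area(PointCloud(x, y, z)) == pytest.approx(
            truth["area_cm2"], rel=0.05)

    def test_collinear_projection_rejected(self):
        x = np.linspace(0, 1, 10)
        with pytest.raises(DegenerateSegmentError):
            leaf_area(PointCloud(x, 2 * x, np.zeros_like(x)))


class TestInvariances:
    def test_translation_invariance(self, rng):
        cloud = ellipse_cloud(10, 4, step=0.1)
        shifted = PointCloud(cloud.x_cm + 123.4, cloud.y_cm - 56.7,
                             cloud.z_cm + 8.9)
        assert leaf_length(shifted) == pytest.approx(leaf_length(cloud),
                                                     rel=0.01)
        assert leaf_width(shifted) == pytest.approx(leaf_width(cloud),
                                                    rel=0.01)

    def test_quarter_turn_swaps_length_and_width(self):
        cloud = ellipse_cloud(10, 4, step=0.05)
        rotated = PointCloud(-cloud.y_cm, cloud.x_cm, cloud.z_cm)
        assert leaf_length(rotated) == pytest.approx(leaf_length(cloud),
                                                     rel=0.01)
        assert leaf_width(rotated) == pytest.approx(leaf_width(cloud),
                                                    rel=0.01)


class TestExtractTraits:
    def test_composition_matches_parts(self):
        cloud = ellipse_cloud(10, 4, step=0.1)
        tr = extract_traits(cloud, label=3)
        assert tr.leaf_label == 3
        assert tr.length_cm == pytest.approx(leaf_length(cloud))
        assert tr.width_cm == pytest.approx(leaf_width(cloud))
        assert tr.area_cm2 == pytest.approx(leaf_area(cloud))

    def test_degenerate_segment_all_missing_with_warning(self):
        tiny = PointCloud([0.0, 1.0], [0.0, 0.0], [0.0, 0.0])
        with pytest.warns(UserWarning):
            tr = extract_traits(tiny, label=1)
        assert np.isnan(tr.length_cm) and np.isnan(tr.width_cm)
        assert np.isnan(tr.area_cm2)
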