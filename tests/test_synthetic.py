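import numpy as np
import pytest
import yaml

from lidarleaf.geometry import ScanGeometry
from lidarleaf.scan_io import GROUND_TRUTH_COLUMNS
from lidarleaf.synthetic import (LeafSpec, NoiseModel, SyntheticScene,
                                 demo_scene, make_leaf,
                                 pan_tilt_geometry_for_scene,
                                 rail_geometry_for_scene, scene_from_dict,
                                 scene_ground_truth, scene_to_dict,
                                 simulate_scan)


class TestMakeLeaf:
    def test_flat_leaf_truth(self):
        mesh, truth = make_leaf(LeafSpec(10.0, 4.0), n_axial=96, n_lateral=32)
        assert truth["length_cm"] == 10.0
        assert truth["width_cm"] == 4.0
        # elliptical planform: mesh area approaches pi * 5 * 2
        assert truth["area_cm2"] == pytest.approx(np.pi * 5 * 2, rel=0.005)

    def test_flat_leaf_coplanar(self):
        mesh, _ = make_leaf(LeafSpec(10.0, 4.0, bend_coefficient=0.0,
                                     center=(0, 0, 60.0)))
        np.testing.assert_allclose(mesh.vertices[:, 2], 60.0, atol=1e-12)

    def test_bend_lengthens_midline(self):
        _, flat = make_leaf(LeafSpec(10.0, 4.0, 0.0))
        _, bent = make_leaf(LeafSpec(10.0, 4.0, 0.08))
        assert bent["length_cm"] > flat["length_cm"]
        assert bent["length_cm"] > 10.0  # arc exceeds chord

    def test_no_degenerate_triangles(self):
        mesh, _ = make_leaf(LeafSpec(12.0, 6.0, 0.05, yaw_deg=30.0))
        areas = mesh.area_faces
        assert np.all(areas > 0)

    def test_yaw_and_center_are_rigid(self):
        _, base = make_leaf(LeafSpec(12.0, 6.0, 0.03))
        _, moved = make_leaf(LeafSpec(12.0, 6.0, 0.03, yaw_deg=77.0,
                                      center=(30.0, -10.0, 55.0)))
        for k in ("length_cm", "width_cm", "area_cm2"):
            assert moved[k] == pytest.approx(base[k], rel=1e-9)


class TestGroundTruthTable:
    def test_schema_and_row_count(self):
        scene = demo_scene()
        table = scene_ground_truth(scene)
        assert list(table.columns) == GROUND_TRUTH_COLUMNS
        assert len(table) == len(scene.leaves)
        assert list(table["leaf_id"]) == [1, 2, 3]

    def test_empty_scene_empty_table(self):
        table = scene_ground_truth(SyntheticScene(leaves=[]))
        assert len(table) == 0


class TestSimulateScan:
    def perpendicular_geometry(self):
        # single beam straight down the depth axis: phi=90, theta=90
        return ScanGeometry("pan_tilt", azimuth_deg=[90.0],
                            elevation_deg=[90.0])

    def test_plane_range_analytic(self):
        scene = SyntheticScene(leaves=[], ground_z_cm=100.0)
        grid = simulate_scan(scene, self.perpendicular_geometry())
        assert grid.range_cm[0, 0] == pytest.approx(100.0, abs=1e-6)
        assert grid.reflectance[0, 0] == pytest.approx(
            scene.ground_reflectance_mean)

    def test_same_seed_identical_grids(self):
        scene = demo_scene()
        geom = pan_tilt_geometry_for_scene(scene, 2.0, 2.0)
        noise = NoiseModel(range_sigma_cm=0.3, outlier_rate=0.05,
                           reflectance_sigma=1.0, seed=42)
        a = simulate_scan(scene, geom, noise)
        b = simulate_scan(scene, geom, noise)
        np.testing.assert_array_equal(a.range_cm, b.range_cm)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)

    def test_different_seed_differs(self):
        scene = demo_scene()
        geom = pan_tilt_geometry_for_scene(scene, 2.0, 2.0)
        a = simulate_scan(scene, geom, NoiseModel(range_sigma_cm=0.3, seed=1))
        b = simulate_scan(scene, geom, NoiseModel(range_sigma_cm=0.3, seed=2))
        assert not np.array_equal(a.range_cm, b.range_cm)

    def test_outlier_count_binomial(self):
        # ~10,000 rays all hitting the ground plane
        scene = SyntheticScene(leaves=[], ground_z_cm=80.0)
        geom = ScanGeometry("pan_tilt",
                            azimuth_deg=np.linspace(80, 100, 100),
                            elevation_deg=np.linspace(80, 100, 100))
        p = 0.1
        count, n = 0, 0
        for seed in range(10):
            grid, diag = simulate_scan(scene, geom,
                                       NoiseModel(outlier_rate=p, seed=seed),
                                       return_diagnostics=True)
            count += int(diag.outlier.sum())
            n += grid.range_cm.size
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(count - n * p) < 3 * sigma

    def test_outliers_displaced_far_from_surface(self):
        scene = SyntheticScene(leaves=[], ground_z_cm=80.0)
        geom = self.perpendicular_geometry()
        noise = NoiseModel(outlier_rate=1.0, outlier_magnitude_cm=15.0, seed=5)
        grid, diag = simulate_scan(scene, geom, noise,
                                   return_diagnostics=True)
        assert diag.outlier[0, 0]
        assert 7.5 <= abs(grid.range_cm[0, 0] - 80.0) <= 22.5

    def test_grazing_beams_dropped(self):
        # a leaf seen nearly edge-on drops out under the grazing rule
        scene = SyntheticScene(
            leaves=[LeafSpec(10.0, 4.0, center=(0.0, 100.0, 60.0))],
            ground_z_cm=1000.0)
        # beam at ~31 degrees to the leaf plane
        geom = ScanGeometry("pan_tilt", azimuth_deg=[90.0],
                            elevation_deg=[np.rad2deg(np.arctan2(60, 100))])
        clean, d0 = simulate_scan(scene, geom, NoiseModel(),
                                  return_diagnostics=True)
        assert d0.object_id[0, 0] == 1
        strict, d1 = simulate_scan(
            scene, geom, NoiseModel(edge_dropout_deg=40.0),
            return_diagnostics=True)
        assert d1.object_id[0, 0] == -1 and np.isnan(strict.range_cm[0, 0])

    def test_sparse_pan_tilt_fewer_points_than_dense_rail(self):
        scene = demo_scene()
        rail_geom, n_lines = rail_geometry_for_scene(scene)
        rail = simulate_scan(scene, rail_geom, n_lines=n_lines)
        pt_geom = pan_tilt_geometry_for_scene(scene, 0.5, 0.5)
        pt = simulate_scan(scene, pt_geom)
        _, rail_diag = simulate_scan(scene, rail_geom, n_lines=n_lines,
                                     return_diagnostics=True)
        _, pt_diag = simulate_scan(scene, pt_geom, return_diagnostics=True)
        assert (pt_diag.object_id > 0).sum() < (rail_diag.object_id > 0).sum()
        assert np.isfinite(pt.range_cm).sum() < np.isfinite(rail.range_cm).sum()


class TestSceneSerialisation:
    def test_yaml_round_trip(self, tmp_path):
        scene = demo_scene(bend=0.03)
        path = tmp_path / "scene.yaml"
        path.write_text(yaml.safe_dump(scene_to_dict(scene)))
        back = scene_from_dict(yaml.safe_load(path.read_text()))
        assert back.leaves == scene.leaves
        assert back.ground_z_cm == scene.ground_z_cm
        assert back.plant_id == scene.plant_id
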