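"""Curvature estimation and the four 3D shape metrics against closed-form
differential geometry on spheres, cylinders, saddles, tori, cubes, cones."""

import numpy as np
import pytest
import trimesh

from conftest import open_cylinder, saddle_patch
from viscperc.mesh_metrics import (DegenerateDesignError, extract_metrics,
                                   frame_metrics, metric_angular_curvature,
                                   metric_com_height, metric_flatness,
                                   metric_total_abs_curvature,
                                   principal_curvatures, shape_index)
from viscperc.synth import MeshFrame, SceneConfig, generate_liquid_sequence


class TestPrincipalCurvatures:
    def test_unit_sphere_curvatures(self, icosphere):
        f = principal_curvatures(icosphere)
        ok = f.defined
        assert np.nanmedian(f.k1[ok]) == pytest.approx(1.0, rel=0.05)
        assert np.nanmedian(f.k2[ok]) == pytest.approx(1.0, rel=0.05)

    def test_cylinder_curvatures(self, cylinder_r2):
        f = principal_curvatures(cylinder_r2)
        ok = f.defined
        assert np.nanmedian(f.k1[ok]) == pytest.approx(0.5, rel=0.05)
        assert abs(np.nanmedian(f.k2[ok])) < 0.025

    def test_saddle_at_origin(self):
        frame = saddle_patch()
        f = principal_curvatures(frame)
        origin = np.argmin(np.linalg.norm(frame.vertices[:, :2], axis=1))
        assert f.k1[origin] == pytest.approx(2.0, rel=0.05)
        assert f.k2[origin] == pytest.approx(-2.0, rel=0.05)

    def test_boundary_vertices_flagged(self):
        frame = saddle_patch(n=15)
        f = principal_curvatures(frame)
        # the patch border must be flagged, the interior must not
        assert f.boundary.sum() == 4 * 15 - 4
        assert not f.defined[f.boundary].any()

    def test_area_weights_sum_to_surface_area(self, icosphere):
        f = principal_curvatures(icosphere)
        mesh = trimesh.Trimesh(icosphere.vertices, icosphere.faces, process=False)
        assert f.area_weights.sum() == pytest.approx(mesh.area, rel=1e-6)
        assert (f.area_weights > 0).all()

    def test_too_few_neighbors_marked_undefined(self):
        # a single triangle: every vertex is boundary with 2 neighbors
        frame = MeshFrame(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
                          np.array([[0, 1, 2]]))
        f = principal_curvatures(frame)
        assert np.isnan(f.k1).all()


class TestShapeIndex:
    def test_convex_umbilic_is_one(self):
        assert shape_index(np.array([1.0]), np.array([1.0]))[0] == 1.0

    def test_symmetric_saddle_is_zero(self):
        assert shape_index(np.array([2.0]), np.array([-2.0]))[0] == 0.0

    def test_cylinder_is_half(self):
        assert shape_index(np.array([1.0]), np.array([0.0]))[0] == pytest.approx(0.5)

    def test_flat_point_is_zero(self):
        assert shape_index(np.array([1e-12]), np.array([-1e-12]))[0] == 0.0

    def test_concave_umbilic_is_minus_one(self):
        assert shape_index(np.array([-1.0]), np.array([-1.0]))[0] == -1.0

    def test_range_bounded(self, icosphere):
        f = principal_curvatures(icosphere)
        S = f.shape_index[f.defined]
        assert np.all(S >= -1.0) and np.all(S <= 1.0)


class TestMetrics:
    def test_m1_unit_sphere(self, icosphere):
        f = principal_curvatures(icosphere)
        assert metric_angular_curvature(f) == pytest.approx(1.0, rel=0.05)

    def test_m1_scaling_covariance(self, icosphere):
        # H scales as 1/s, S is scale-invariant
        f1 = principal_curvatures(icosphere)
        scaled = MeshFrame(icosphere.vertices * 2.0, icosphere.faces)
        f2 = principal_curvatures(scaled)
        assert metric_angular_curvature(f2) == \
            pytest.approx(metric_angular_curvature(f1) / 2.0, rel=0.02)

    def test_m2_horizontal_unit_square(self):
        frame = MeshFrame(np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float),
                          np.array([[0, 1, 2], [0, 2, 3]]))
        assert metric_flatness(frame) == pytest.approx(1.0)

    def test_m2_vertical_plane_is_zero(self):
        frame = MeshFrame(np.array([[0, 0, 0], [1, 0, 0], [1, 0, 1], [0, 0, 1]], float),
                          np.array([[0, 1, 2], [0, 2, 3]]))
        assert metric_flatness(frame) == pytest.approx(0.0, abs=1e-12)

    def test_m2_unit_sphere_integral(self, icosphere):
        # integral of |cos(theta)| over the unit sphere is 2*pi
        assert metric_flatness(icosphere) == pytest.approx(2 * np.pi, rel=0.05)

    def test_m3_translated_sphere(self, icosphere):
        frame = MeshFrame(icosphere.vertices + [0, 0, 3.0], icosphere.faces)
        z, volumetric = metric_com_height(frame)
        assert volumetric and z == pytest.approx(3.0, abs=1e-6)

    def test_m3_unit_cube(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        frame = MeshFrame(np.asarray(box.vertices) + 0.5, np.asarray(box.faces))
        z, volumetric = metric_com_height(frame)
        assert volumetric and z == pytest.approx(0.5, abs=1e-9)

    def test_m3_cone_centroid(self):
        cone = trimesh.creation.cone(radius=1.0, height=2.0, sections=64)
        frame = MeshFrame(np.asarray(cone.vertices), np.asarray(cone.faces))
        z, volumetric = metric_com_height(frame)
        assert volumetric and z == pytest.approx(2.0 / 4.0, rel=0.01)

    def test_m3_open_mesh_falls_back_to_surface_centroid(self):
        frame = saddle_patch(n=15)
        _, volumetric = metric_com_height(frame)
        assert not volumetric

    def test_m4_sphere_gauss_bonnet(self, icosphere):
        f = principal_curvatures(icosphere)
        assert metric_total_abs_curvature(f) == pytest.approx(4 * np.pi, rel=0.05)

    def test_m4_scale_invariant(self, icosphere):
        scaled = MeshFrame(icosphere.vertices * 3.0, icosphere.faces)
        f = principal_curvatures(scaled)
        assert metric_total_abs_curvature(f) == pytest.approx(4 * np.pi, rel=0.05)

    def test_m4_torus(self, torus_2_05):
        # integral of |K| over any torus is 8*pi
        f = principal_curvatures(torus_2_05)
        assert metric_total_abs_curvature(f) == pytest.approx(8 * np.pi, rel=0.05)

    def test_rigid_motion_invariance_m1_m4(self, icosphere):
        R = trimesh.transformations.rotation_matrix(0.7, [1, 2, 3])[:3, :3]
        moved = MeshFrame(icosphere.vertices @ R.T + [1.0, -2.0, 0.5],
                          icosphere.faces)
        f0 = principal_curvatures(icosphere)
        f1 = principal_curvatures(moved)
        assert metric_angular_curvature(f1) == \
            pytest.approx(metric_angular_curvature(f0), rel=0.01)
        assert metric_total_abs_curvature(f1) == \
            pytest.approx(metric_total_abs_curvature(f0), rel=0.01)

    def test_m3_translation_covariance(self, icosphere):
        up = MeshFrame(icosphere.vertices + [0, 0, 1.25], icosphere.faces)
        z0, _ = metric_com_height(icosphere)
        z1, _ = metric_com_height(up)
        assert z1 - z0 == pytest.approx(1.25, abs=1e-9)

    def test_m2_invariant_under_z_rotation(self, icosphere):
        R = trimesh.transformations.rotation_matrix(1.1, [0, 0, 1])[:3, :3]
        rot = MeshFrame(icosphere.vertices @ R.T, icosphere.faces)
        assert metric_flatness(rot) == pytest.approx(metric_flatness(icosphere),
                                                     rel=1e-6)


class TestExtractMetrics:
    def _sequences(self, viscosities, n_frames=24, grid_n=20):
        return [generate_liquid_sequence(SceneConfig("pouring"), v,
                                         n_frames=n_frames, seed=0, grid_n=grid_n)
                for v in viscosities]

    def test_two_point_zscore(self):
        seqs = self._sequences([0.01, 1.0])
        df = extract_metrics(seqs, frame_step=6, dry_height=1e-5)
        z = np.sort(df["m3_com_height_z"].to_numpy())
        np.testing.assert_allclose(z, [-1.0, 1.0], atol=1e-9)

    def test_duplicated_stimuli_raise_zero_variance(self):
        seqs = self._sequences([0.05, 0.05])
        with pytest.raises(DegenerateDesignError):
            extract_metrics(seqs, frame_step=6, dry_height=1e-5)

    def test_single_stimulus_raises(self):
        seqs = self._sequences([0.05])
        with pytest.raises(DegenerateDesignError):
            extract_metrics(seqs, frame_step=6, dry_height=1e-5)

    def test_per_time_period_shape_and_family_normalization(self):
        seqs = self._sequences([0.01, 1.0], n_frames=36)
        df = extract_metrics(seqs, aggregation="per_time_period", n_periods=6,
                             frame_step=3, dry_height=1e-5)
        assert len(df) == 12  # 2 families x 6 periods
        for _, fam in df.groupby("sequence"):
            med = fam["m2_flatness"].median()
            assert med == pytest.approx(1.0, rel=1e-9)

    def test_constant_sequence_full_mode_returns_frame_value(self, icosphere):
        from viscperc.synth import MeshSequence
        ref = frame_metrics(icosphere)
        seqs = [
            MeshSequence([icosphere] * 3, 30.0, 0.01, SceneConfig("a"), 0),
            MeshSequence([MeshFrame(icosphere.vertices * 2.0 + [0, 0, 1.0],
                                    icosphere.faces)] * 3,
                         30.0, 1.0, SceneConfig("b"), 0),
        ]
        df = extract_metrics(seqs)
        assert df.loc[0, "m1_angular_curvature"] == pytest.approx(
            ref["m1_angular_curvature"], rel=1e-9)
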