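"""Velocity preprocessing, wall sampling and WSS estimation."""

import numpy as np
import pytest

from wallmap.geometry import compute_centerline, compute_diameter_map
from wallmap.synthetic import generate_bifurcation_mesh, generate_velocity_image
from wallmap.units import poiseuille_wss_pa
from wallmap.wss import (
    compute_wss_map,
    correct_background_offset,
    fit_wall_gradient,
    sample_wall_velocities,
    static_tissue_mask,
)


@pytest.fixture(scope="module")
def tube_with_diameter(straight_tube):
    mesh, branches = straight_tube
    dmap = compute_diameter_map(mesh, compute_centerline(mesh))
    return mesh, branches, dmap


class TestBackgroundCorrection:
    def test_synthetic_offset_removed(self, straight_tube):
        mesh, branches = straight_tube
        img = generate_velocity_image(
            mesh, 60.0, voxel_mm=(0.5,) * 3, background_offset=(5.0, -2.0, 1.0),
            branches=branches,
        )
        mask = static_tissue_mask(img, mesh)
        corrected = correct_background_offset(img, mask)
        assert corrected.corrected
        residual = corrected.data[mask].mean(axis=0)
        np.testing.assert_allclose(residual, 0.0, atol=1e-9)

    def test_zero_offset_image_unchanged(self, straight_tube, tube_velocity):
        mesh, _ = straight_tube
        mask = static_tissue_mask(tube_velocity, mesh)
        corrected = correct_background_offset(tube_velocity, mask)
        np.testing.assert_allclose(corrected.data, tube_velocity.data, atol=1e-9)

    def test_empty_mask_rejected(self, tube_velocity):
        with pytest.raises(ValueError, match="empty"):
            correct_background_offset(
                tube_velocity, np.zeros(tube_velocity.shape, dtype=bool)
            )

    def test_offset_then_correction_leaves_wss_nearly_unchanged(self, tube_with_diameter):
        mesh, branches, dmap = tube_with_diameter
        clean = generate_velocity_image(mesh, 60.0, voxel_mm=(0.5,) * 3, branches=branches)
        offset = generate_velocity_image(
            mesh, 60.0, voxel_mm=(0.5,) * 3, background_offset=(5.0, 0.0, 0.0),
            branches=branches,
        )
        corrected = correct_background_offset(offset, static_tissue_mask(offset, mesh))
        wss_clean = compute_wss_map(mesh, clean, dmap).values
        wss_corr = compute_wss_map(mesh, corrected, dmap).values
        ok = np.isfinite(wss_clean) & np.isfinite(wss_corr) & (wss_clean > 0.1)
        rel = np.abs(wss_corr[ok] - wss_clean[ok]) / wss_clean[ok]
        assert np.median(rel) < 0.02


class TestWallSampling:
    def test_innermost_sample_reaches_peak_velocity(self, tube_with_diameter, tube_velocity):
        mesh, _, dmap = tube_with_diameter
        samples = sample_wall_velocities(mesh, tube_velocity, dmap)
        speeds = np.linalg.norm(samples.in_plane_velocities, axis=2)
        # innermost sample (index 2) sits at the tube centerline
        assert np.median(speeds[:, 2]) == pytest.approx(60.0, rel=0.03)

    def test_wall_sample_near_zero_no_slip(self, tube_with_diameter, tube_velocity):
        mesh, _, dmap = tube_with_diameter
        samples = sample_wall_velocities(mesh, tube_velocity, dmap)
        speeds = np.linalg.norm(samples.in_plane_velocities, axis=2)
        assert np.median(speeds[:, 0]) < 0.10 * 60.0

    def test_out_of_bounds_vertices_excluded_not_mapped(self, tube_with_diameter):
        mesh, branches, dmap = tube_with_diameter
        img = generate_velocity_image(
            mesh, 60.0, voxel_mm=(0.5,) * 3, branches=branches, margin_mm=4.0
        )
        # crop the image so part of the tube pokes out of the volume
        cropped_data = img.data[:, :, : img.shape[2] // 2]
        from wallmap.core import VelocityImage

        cropped = VelocityImage(cropped_data, img.affine.copy())
        samples = sample_wall_velocities(mesh, cropped, dmap)
        assert len(samples.excluded) > 0
        assert set(samples.excluded).isdisjoint(set(samples.vertex_ids))
        assert len(samples.excluded) + len(samples.vertex_ids) == mesh.n_vertices


class TestWallGradient:
    def test_parabolic_profile_derivative_closed_form(self):
        # v = 60*(1 - ((3-d)/3)^2) sampled at d = 0, 1.5, 3 mm:
        # derivative at the wall is 40 (cm/s)/mm = 400 1/s
        d = np.array([0.0, 1.5, 3.0])
        v = np.column_stack([[0.0, 45.0, 60.0], [0.0, 0.0, 0.0]])
        assert fit_wall_gradient(d, v) == pytest.approx(400.0, rel=1e-9)

    def test_constant_velocity_zero_gradient(self):
        d = np.array([0.0, 1.5, 3.0])
        v = np.column_stack([[7.0, 7.0, 7.0], [1.0, 1.0, 1.0]])
        assert fit_wall_gradient(d, v) == pytest.approx(0.0, abs=1e-9)

    def test_linear_profile_reproduced_exactly(self):
        d = np.array([0.0, 1.0, 2.0])
        v = np.column_stack([3.0 * d, np.zeros(3)])  # 3 (cm/s)/mm -> 30 1/s
        assert fit_wall_gradient(d, v) == pytest.approx(30.0, rel=1e-9)

    def test_coincident_distances_rejected(self):
        with pytest.raises(ValueError):
            fit_wall_gradient(np.array([0.0, 1.0, 1.0]), np.zeros((3, 2)))


class TestWssMap:
    def test_poiseuille_closed_form(self, tube_with_diameter, tube_velocity):
        mesh, _, dmap = tube_with_diameter
        wss = compute_wss_map(mesh, tube_velocity, dmap, viscosity=3.2e-3)
        truth = poiseuille_wss_pa(60.0, 3.0, 3.2e-3)
        assert truth == pytest.approx(1.28)
        est = wss.values[np.isfinite(wss.values)]
        assert np.median(np.abs(est - truth) / truth) <= 0.10

    def test_linearity_in_velocity(self, tube_with_diameter, straight_tube, tube_velocity):
        from wallmap.core import VelocityImage

        mesh, _, dmap = tube_with_diameter
        doubled = VelocityImage(2.0 * tube_velocity.data, tube_velocity.affine.copy())
        w1 = compute_wss_map(mesh, tube_velocity, dmap).values
        w2 = compute_wss_map(mesh, doubled, dmap).values
        ok = np.isfinite(w1) & (w1 > 1e-12)
        np.testing.assert_allclose(w2[ok], 2.0 * w1[ok], rtol=1e-6)

    def test_zero_velocity_gives_zero_wss(self, tube_with_diameter, tube_velocity):
        from wallmap.core import VelocityImage

        mesh, _, dmap = tube_with_diameter
        zero = VelocityImage(np.zeros_like(tube_velocity.data), tube_velocity.affine.copy())
        w = compute_wss_map(mesh, zero, dmap).values
        np.testing.assert_allclose(w[np.isfinite(w)], 0.0, atol=1e-12)

    def test_nonpositive_viscosity_rejected(self, tube_with_diameter, tube_velocity):
        mesh, _, dmap = tube_with_diameter
        with pytest.raises(ValueError, match="viscosity"):
            compute_wss_map(mesh, tube_velocity, dmap, viscosity=0.0)

    def test_rotation_invariance(self, straight_tube, tube_velocity, tube_with_diameter):
        # rotate mesh and image (data components + affine) together: the
        # estimator must see an identical problem in the rotated frame
        from wallmap.core import ScalarMap, VelocityImage

        mesh, _, dmap = tube_with_diameter
        theta = np.deg2rad(30)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(theta), -np.sin(theta)], [0, np.sin(theta), np.cos(theta)]]
        )
        moved = mesh.transformed(rot, np.zeros(3))
        affine = tube_velocity.affine.copy()
        affine[:3, :3] = rot @ affine[:3, :3]
        affine[:3, 3] = rot @ affine[:3, 3]
        rotated_img = VelocityImage(tube_velocity.data @ rot.T, affine)
        d_moved = ScalarMap(moved, dmap.values.copy(), "D")
        w0 = compute_wss_map(mesh, tube_velocity, dmap).values
        w1 = compute_wss_map(moved, rotated_img, d_moved).values
        ok = np.isfinite(w0) & np.isfinite(w1) & (w0 > 0.1)
        rel = np.abs(w1[ok] - w0[ok]) / w0[ok]
        assert np.median(rel) < 0.01
        assert np.max(rel) < 0.01

    def test_missing_plus_estimated_covers_all_vertices(self, tube_with_diameter, tube_velocity):
        mesh, _, dmap = tube_with_diameter
        samples = sample_wall_velocities(mesh, tube_velocity, dmap)
        wss = compute_wss_map(mesh, tube_velocity, dmap, samples=samples)
        n_est = np.count_nonzero(np.isfinite(wss.values))
        assert n_est + len(samples.excluded) == mesh.n_vertices
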