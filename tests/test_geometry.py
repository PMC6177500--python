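"""Wall-thickness, centerline and diameter map extraction."""

import numpy as np
import pytest

from wallmap.core import ScalarMap, VesselMesh
from wallmap.geometry import (
    compute_centerline,
    compute_diameter_map,
    compute_wall_thickness,
)
from wallmap.meshdist import SurfaceDistance, closest_point_on_triangles
from wallmap.synthetic import generate_bifurcation_mesh


def _torus_segment_mesh(major=20.0, minor=3.0, sweep_deg=70.0, pitch=0.5):
    """Bent-tube test surface: a capped torus segment via marching cubes."""
    import trimesh
    from skimage import measure

    sweep = np.deg2rad(sweep_deg)
    lo = np.array([-1.0, -minor - 1.0, -minor - 1.0])
    hi = np.array([major + minor + 1.0, (major + minor) * np.sin(sweep) + minor + 1.0,
                   minor + 1.0])
    dims = np.ceil((hi - lo) / pitch).astype(int) + 1
    xs, ys, zs = (lo[k] + pitch * np.arange(dims[k]) for k in range(3))
    g = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    torus = np.hypot(np.hypot(g[:, 0], g[:, 1]) - major, g[:, 2]) - minor
    cut_lo = -g[:, 1]  # keep the half-space y >= 0
    n_hi = np.array([-np.sin(sweep), np.cos(sweep), 0.0])
    cut_hi = g @ n_hi  # keep angle <= sweep
    sdf = np.maximum.reduce([torus, cut_lo, cut_hi]).reshape(dims)
    verts, faces, _, _ = measure.marching_cubes(sdf, 0.0, spacing=(pitch,) * 3)
    verts = verts + lo
    tm = trimesh.Trimesh(verts, faces, process=False)
    tm.fix_normals()
    verts, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
    caps = (np.abs(verts[:, 1]) < 1.3 * pitch) | (
        np.abs(verts @ n_hi) < 1.3 * pitch
    )
    return VesselMesh(
        vertices=verts,
        faces=faces,
        branch_label=np.zeros(len(verts), dtype=int),
        cap_mask=caps,
    )


class TestMeshDistance:
    def test_closest_point_on_single_triangle_regions(self):
        tri = np.array([[[0, 0, 0], [1, 0, 0], [0, 1, 0]]], dtype=float)
        cases = {
            (0.25, 0.25, 1.0): (0.25, 0.25, 0.0),  # face interior
            (-1.0, -1.0, 0.0): (0.0, 0.0, 0.0),  # vertex A
            (2.0, 0.0, 0.0): (1.0, 0.0, 0.0),  # vertex B
            (0.5, -1.0, 0.0): (0.5, 0.0, 0.0),  # edge AB
            (1.0, 1.0, 0.0): (0.5, 0.5, 0.0),  # edge BC
        }
        for p, expected in cases.items():
            got = closest_point_on_triangles(np.array([p], dtype=float), tri)[0]
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_signed_distance_on_tube_interior_points(self, straight_tube):
        mesh, _ = straight_tube
        sd = SurfaceDistance(mesh)
        pts = np.array([[0.0, 0.0, -7.5], [1.0, 0.0, -5.0], [0.0, 0.0, -1.0]])
        s = sd.signed_distance(pts)
        assert np.all(s > 0)
        assert s[0] == pytest.approx(3.0, abs=0.1)
        outside = sd.signed_distance(np.array([[6.0, 0.0, -7.5]]))
        assert outside[0] == pytest.approx(-3.0, abs=0.1)


class TestWallThickness:
    def test_concentric_cylinders_give_annulus_width(self):
        lumen = generate_bifurcation_mesh(radii={"cca": 3.0}, lengths={"cca": 15.0}, pitch=0.5)
        outer = generate_bifurcation_mesh(radii={"cca": 4.0}, lengths={"cca": 17.0}, pitch=0.5)
        outer = outer.transformed(np.eye(3), np.array([0.0, 0.0, 1.0]))
        wt = compute_wall_thickness(lumen, outer)
        non_cap = ~lumen.cap_mask
        tol = 0.02 * 1.0 + lumen.mean_edge_length
        assert np.all(np.abs(wt.values[non_cap] - 1.0) < tol)
        # far tighter in practice: the median is within a few microns
        assert abs(np.median(wt.values[non_cap]) - 1.0) < 0.02

    def test_coincident_surfaces_rejected(self, straight_tube):
        mesh, _ = straight_tube
        with pytest.raises(ValueError):
            compute_wall_thickness(mesh, mesh)  # WT ~ 0 violates positivity

    def test_outer_wall_crossing_lumen_reported(self):
        lumen = generate_bifurcation_mesh(radii={"cca": 3.0}, lengths={"cca": 15.0}, pitch=0.6)
        inner = generate_bifurcation_mesh(radii={"cca": 2.0}, lengths={"cca": 15.0}, pitch=0.6)
        with pytest.raises(ValueError, match="intersects the lumen"):
            compute_wall_thickness(lumen, inner)

    def test_rigid_invariance(self, small_cohort):
        s = small_cohort[0]
        wt0 = compute_wall_thickness(s.lumen, s.outer_wall)
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        t = np.array([5.0, -3.0, 2.0])
        wt1 = compute_wall_thickness(
            s.lumen.transformed(rot, t), s.outer_wall.transformed(rot, t)
        )
        np.testing.assert_allclose(wt1.values, wt0.values, atol=1e-6)


class TestCenterline:
    def test_straight_cylinder_centerline_on_axis(self, straight_tube):
        mesh, _ = straight_tube
        cl = compute_centerline(mesh)
        pts = cl.all_points()
        assert np.all(np.hypot(pts[:, 0], pts[:, 1]) < 0.2)
        assert np.all(np.abs(cl.all_radii() - 3.0) < 0.15)

    def test_bifurcation_returns_two_outlet_paths(self, bifurcation):
        mesh, _ = bifurcation
        cl = compute_centerline(mesh)
        assert set(cl.points) == {"ICA", "ECA"}
        for pts in cl.points.values():
            assert len(pts) >= 2

    def test_bent_tube_radii_constant(self):
        mesh = _torus_segment_mesh()
        cl = compute_centerline(mesh)
        radii = cl.all_radii()
        assert np.all(np.abs(radii - 3.0) / 3.0 < 0.05)


class TestDiameterMap:
    def test_straight_cylinder_diameter(self, straight_tube):
        mesh, _ = straight_tube
        dmap = compute_diameter_map(mesh, compute_centerline(mesh))
        non_cap = ~mesh.cap_mask
        assert np.all(np.abs(dmap.values[non_cap] - 6.0) / 6.0 < 0.05)

    def test_tapered_tube_diameter_monotone_along_axis(self):
        mesh = generate_bifurcation_mesh(
            radii={"cca": 3.0}, lengths={"cca": 18.0}, tapers={"cca": 0.3}, pitch=0.5
        )
        dmap = compute_diameter_map(mesh, compute_centerline(mesh))
        wall = ~mesh.cap_mask
        z = mesh.vertices[wall, 2]
        d = dmap.values[wall]
        # radius narrows towards the far (negative-z) end: bin along z and
        # require the binned medians to increase with z
        edges = np.linspace(z.min() + 1, z.max() - 1, 8)
        medians = [
            np.median(d[(z >= a) & (z < b)]) for a, b in zip(edges[:-1], edges[1:])
        ]
        assert np.all(np.diff(medians) > 0)

    def test_empty_centerline_rejected(self, straight_tube):
        from wallmap.core import Centerline

        mesh, _ = straight_tube
        with pytest.raises(ValueError):
            compute_diameter_map(mesh, Centerline(points={}, radius={}))

    def test_rigid_invariance_of_diameter(self, straight_tube):
        mesh, _ = straight_tube
        d0 = compute_diameter_map(mesh, compute_centerline(mesh))
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = mesh.transformed(rot, np.array([1.0, 2.0, 3.0]))
        d1 = compute_diameter_map(moved, compute_centerline(moved))
        # same algorithm on rigidly moved inputs: identical values up to
        # the (deterministic) binning of identical local coordinates
        np.testing.assert_allclose(d1.values, d0.values, atol=1e-6)


class TestScalarMapInvariants:
    def test_one_value_per_vertex_enforced(self, straight_tube):
        mesh, _ = straight_tube
        with pytest.raises(ValueError):
            ScalarMap(mesh, np.ones(3), "WT")

    def test_positivity_enforced_for_wt_and_d(self, straight_tube):
        mesh, _ = straight_tube
        with pytest.raises(ValueError):
            ScalarMap(mesh, np.zeros(mesh.n_vertices), "WT")
        with pytest.raises(ValueError):
            ScalarMap(mesh, -np.ones(mesh.n_vertices), "WSS")
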