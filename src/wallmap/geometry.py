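"""Per-vertex wall-thickness and diameter maps from vessel surfaces.

Wall thickness is the shortest point-to-surface distance from each lumen
vertex to the outer (adventitial) wall.  The vessel diameter map is
derived from a lumen centerline: each wall vertex is assigned twice its
distance to the nearest centerline point.

The centerline is computed by cross-section centroid chaining: branch
vertices (identified by their labels) are binned along the branch's
principal axis, bin centroids form an initial polyline, and one local
refinement pass re-collects vertices in slabs perpendicular to the
evolving tangent.  The maximal inscribed-sphere radius at each point is
its distance to the lumen surface.
"""

from __future__ import annotations

import warnings
from typing import Dict, List

import numpy as np
from scipy.spatial import cKDTree

from .core import BIFURCATION, BRANCH_NAMES, CCA, Centerline, ScalarMap, VesselMesh
from .meshdist import SurfaceDistance

__all__ = ["compute_wall_thickness", "compute_centerline", "compute_diameter_map"]


def compute_wall_thickness(lumen: VesselMesh, outer: VesselMesh) -> ScalarMap:
    """Shortest distance [mm] from each lumen vertex to the outer wall.

    Distances are point-to-triangle (surface), not point-to-vertex, so
    the result does not depend on the outer mesh's vertex sampling.
    Raises if the outer wall intersects the lumen (lumen vertices found
    outside the outer surface) or if the walls coincide.
    """
    sd = SurfaceDistance(outer)
    dist, _, inside = sd.query(lumen.vertices)
    offending = np.flatnonzero(~inside & (dist > 1e-9))
    if offending.size:
        raise ValueError(
            f"outer wall intersects the lumen: {offending.size} lumen "
            f"vertices lie outside it (first few: {offending[:10].tolist()})"
        )
    return ScalarMap(lumen, dist, "WT")


def _branch_direction(points: np.ndarray) -> np.ndarray:
    """Principal axis of a vertex cloud (unit vector, arbitrary sign)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _refine_polyline(
    polyline: np.ndarray, points: np.ndarray, slab_half_width: float, passes: int = 3
) -> np.ndarray:
    """Re-collect vertices in slabs perpendicular to the local tangent.

    A slab through the interior of a tube cuts a complete ring whose
    vertex centroid lies on the axis (for meshes of uniform surface
    density), so repeated re-collection relaxes the polyline onto the
    centerline even in bends.
    """
    poly = polyline.copy()
    for _ in range(passes):
        tangents = np.gradient(poly, axis=0)
        norms = np.linalg.norm(tangents, axis=1, keepdims=True)
        tangents = tangents / np.maximum(norms, 1e-12)
        new = poly.copy()
        for i, (node, tang) in enumerate(zip(poly, tangents)):
            axial = (points - node) @ tang
            in_slab = np.abs(axial) < slab_half_width
            if np.count_nonzero(in_slab) >= 5:
                new[i] = points[in_slab].mean(axis=0)
        poly = new
    return poly


def _smooth_polyline(poly: np.ndarray, passes: int = 2) -> np.ndarray:
    """Light 1-2-1 smoothing of interior nodes (ends untouched)."""
    p = poly.copy()
    for _ in range(passes):
        q = p.copy()
        q[1:-1] = (p[:-2] + 2 * p[1:-1] + p[2:]) / 4.0
        p = q
    return p


def _extend_arc(segment: np.ndarray, k: int) -> np.ndarray:
    """Continue an ordered polyline segment beyond its last node by ``k``
    nodes, following the best-fit circular arc (straight line when the
    segment is effectively straight).

    Vessel centerlines are locally arc-like, so a circle fitted in the
    segment's own plane (Kasa fit) extrapolates without the noise
    amplification of polynomial continuation.
    """
    c0 = segment.mean(axis=0)
    u_, s_, vt = np.linalg.svd(segment - c0, full_matrices=False)
    e1, e2 = vt[0], vt[1]
    uv = (segment - c0) @ np.column_stack([e1, e2])
    step = float(np.mean(np.linalg.norm(np.diff(segment, axis=0), axis=1)))

    # straightness check: in-plane perpendicular spread vs extent
    if s_[1] < 1e-3 * s_[0] or len(segment) < 5:
        direction = segment[-1] - segment[-2]
        direction /= np.linalg.norm(direction)
        return segment[-1] + np.outer(np.arange(1, k + 1) * step, direction)

    a_mat = np.column_stack([2 * uv[:, 0], 2 * uv[:, 1], np.ones(len(uv))])
    sol, *_ = np.linalg.lstsq(a_mat, (uv**2).sum(axis=1), rcond=None)
    centre = sol[:2]
    radius = float(np.sqrt(sol[2] + centre @ centre))
    if radius > 1e3 * step:  # effectively straight
        direction = segment[-1] - segment[-2]
        direction /= np.linalg.norm(direction)
        return segment[-1] + np.outer(np.arange(1, k + 1) * step, direction)

    theta = np.unwrap(np.arctan2(uv[:, 1] - centre[1], uv[:, 0] - centre[0]))
    dtheta = np.mean(np.diff(theta))
    new_theta = theta[-1] + dtheta * np.arange(1, k + 1)
    new_uv = centre + radius * np.column_stack([np.cos(new_theta), np.sin(new_theta)])
    return c0 + new_uv @ np.vstack([e1, e2])


def _extrapolate_ends(poly: np.ndarray, k: int, m_fit: int = 20) -> np.ndarray:
    """Extend a polyline by ``k`` arc-extrapolated nodes on each side."""
    if k <= 0 or len(poly) < 5:
        return poly
    m = min(m_fit, len(poly))
    head = _extend_arc(poly[:m][::-1], k)[::-1]
    tail = _extend_arc(poly[-m:], k)
    return np.vstack([head, poly, tail])


def _branch_polyline(
    points: np.ndarray,
    orient_from: np.ndarray,
    bin_width: float,
) -> np.ndarray:
    """Ordered centroid polyline through one branch's vertex cloud.

    ``orient_from`` fixes the direction sign (polyline runs away from it).
    Cap-disk vertices are included: their centroid lies on the branch
    axis, so they do not bias the section centroids.
    """
    direction = _branch_direction(points)
    if (points.mean(axis=0) - orient_from) @ direction < 0:
        direction = -direction
    t = (points - orient_from) @ direction
    trim = 0.3 * bin_width
    t_lo, t_hi = t.min() + trim, t.max() - trim
    if t_hi - t_lo < 2 * bin_width:
        raise ValueError("branch too short to extract a centerline")
    edges = np.arange(t_lo, t_hi + bin_width, bin_width)
    centroids = []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (t >= a) & (t < b)
        if np.count_nonzero(sel) >= 5:
            centroids.append(points[sel].mean(axis=0))
    if len(centroids) < 2:
        raise ValueError("too few cross-sections to define a centerline")
    poly = np.array(centroids)

    # estimate the tube radius from the initial polyline, drop the end
    # nodes inside one radius of the ends (their bins cut truncated or
    # oblique rings), refine the clean interior, smooth out centroid
    # noise, then extrapolate the dropped extent back along the local arc
    tree = cKDTree(_densify(poly))
    r_est = float(np.median(tree.query(points)[0]))
    k = int(np.ceil(0.8 * r_est / bin_width)) + 1
    if len(poly) - 2 * k >= 4:
        poly = poly[k : len(poly) - k]
    else:
        k = 0
    poly = _refine_polyline(poly, points, slab_half_width=bin_width / 2)
    poly = _smooth_polyline(poly)
    return _extrapolate_ends(poly, k)


def compute_centerline(lumen: VesselMesh) -> Centerline:
    """Lumen centerline(s) with maximal inscribed-sphere radii.

    Returns one path per outlet, each running from the CCA inlet to the
    outlet; for a bifurcation the paths share the CCA trajectory and the
    junction point.  A single-branch (straight tube) mesh yields one path.
    """
    labels = lumen.branch_label
    non_cap = ~lumen.cap_mask
    present = [
        code
        for code in (0, 1, 2)
        if np.count_nonzero((labels == code) & non_cap) >= 30
    ]
    if not present:
        # unlabeled mesh: treat everything as one branch
        present = [CCA]
        labels = np.full(lumen.n_vertices, CCA)

    bif_sel = (labels == BIFURCATION) & non_cap
    has_bif = np.count_nonzero(bif_sel) >= 10
    junction = lumen.vertices[bif_sel].mean(axis=0) if has_bif else None

    bin_width = max(2.0 * lumen.mean_edge_length, 1.0)
    branch_polys: Dict[int, np.ndarray] = {}
    for code in present:
        pts = lumen.vertices[labels == code]  # caps included, see _branch_polyline
        origin = junction if junction is not None else pts.mean(axis=0)
        branch_polys[code] = _branch_polyline(pts, orient_from=origin, bin_width=bin_width)

    # inscribed radii measured against the true wall only: faces made
    # entirely of cap-disk vertices are artificial closures, not wall
    wall_faces = ~np.all(lumen.cap_mask[lumen.faces], axis=1)
    wall = VesselMesh(
        lumen.vertices,
        lumen.faces[wall_faces],
        lumen.branch_label,
        cap_mask=lumen.cap_mask,
    )
    sd = SurfaceDistance(wall)
    sd_closed = SurfaceDistance(lumen)

    def inside_filter(points: np.ndarray) -> np.ndarray:
        """Drop end nodes nudged past a cap plane; fail on real escapes."""
        signed = sd_closed.signed_distance(points)
        outside = signed <= 0
        if outside.mean() > 0.2:
            raise ValueError(
                f"{int(outside.sum())} centerline points fell outside the lumen"
            )
        return points[~outside]

    def radii_of(points: np.ndarray) -> np.ndarray:
        return sd.distance(points)

    paths: Dict[str, np.ndarray] = {}
    radii: Dict[str, np.ndarray] = {}
    daughters = [c for c in present if c != CCA]
    if CCA in branch_polys and daughters and junction is not None:
        cca = branch_polys[CCA][::-1]  # inlet -> junction
        for code in daughters:
            full = inside_filter(
                np.vstack([cca, junction[None, :], branch_polys[code]])
            )
            name = BRANCH_NAMES[code]
            paths[name] = full
            radii[name] = radii_of(full)
    else:
        for code in branch_polys:
            name = BRANCH_NAMES[code]
            paths[name] = inside_filter(branch_polys[code])
            radii[name] = radii_of(paths[name])
    if not paths:
        raise ValueError("no centerline paths could be constructed")
    return Centerline(points=paths, radius=radii)


def _densify(path: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Resample a polyline at roughly ``step`` mm spacing."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.ceil(arclen[-1] / step)) + 1, 2)
    s = np.linspace(0.0, arclen[-1], n)
    return np.column_stack([np.interp(s, arclen, path[:, k]) for k in range(3)])


def compute_diameter_map(lumen: VesselMesh, cl: Centerline) -> ScalarMap:
    """Diameter map: 2x the distance from each vertex to the centerline.

    The nearest centerline point is taken over all branches (paths are
    concatenated in sorted branch-name order; exact ties therefore
    resolve to the first branch in that order).
    """
    if not cl.points:
        raise ValueError("empty centerline")
    dense = np.vstack([_densify(cl.points[k]) for k in sorted(cl.points)])
    tree = cKDTree(dense)
    dist, _ = tree.query(lumen.vertices)
    if np.any(dist <= 0):
        warnings.warn("some vertices coincide with the centerline", stacklevel=2)
        dist = np.maximum(dist, 1e-9)
    return ScalarMap(lumen, 2.0 * dist, "D")
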