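"""Synthetic carotid-bifurcation cohorts with known ground truth.

Each subject consists of a lumen surface mesh, an outer-wall surface
mesh and (optionally) a 3-component velocity volume, generated so that
every quantity the analysis estimates is known exactly:

* geometry: a CCA trunk splitting into ICA and ECA daughter branches,
  built as the zero level set of a union of capped-cylinder signed
  distance fields, triangulated by marching cubes;
* flow: steady, per-branch parabolic (Poiseuille) axial velocity
  profiles blended by a smooth partition of unity near the junction;
* wall shear stress: the closed form 2*mu*v_peak/R of Poiseuille flow,
  exact on straight segments;
* wall thickness: the linear interaction model
  ``WT = b0 + b1*WSS + b2*D + b3*WSS*D + eps`` with configurable i.i.d.
  (optionally spatially smoothed) Gaussian vertex noise, clipped to a
  0.1 mm physical floor;
* outer wall: the lumen surface offset outward by the truth WT.

All randomness flows from one master seed through documented
``numpy.random.SeedSequence`` stream splitting: the master sequence is
spawned once per subject, and each subject's sequence is spawned into
(geometry, wall-noise, velocity-noise) streams, in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure

from .core import BIFURCATION, CCA, ECA, ICA, ScalarMap, VelocityImage, VesselMesh
from .units import poiseuille_wss_pa

__all__ = [
    "BranchSpec",
    "CohortConfig",
    "SyntheticSubject",
    "generate_bifurcation_mesh",
    "generate_velocity_image",
    "generate_cohort",
]

_BRANCH_CODE = {"cca": CCA, "ica": ICA, "eca": ECA}

# Nominal geometry of an elderly carotid bifurcation: CCA radius ~3 mm at
# the bulb, ICA slightly larger than ECA, daughters splayed in the x-z
# plane.  Radii are quoted at the junction end; tapers narrow each branch
# towards its free end (CCA inlet, ICA/ECA outlets), which together with
# flow conservation makes WSS, D and WSS*D vary independently along the
# vessel.  Tapers apply to the default carotid geometry only; explicitly
# specified radii default to untapered branches.
DEFAULT_RADII = {"cca": 3.0, "ica": 2.4, "eca": 2.0}
DEFAULT_ANGLES = {"ica": 25.0, "eca": -35.0}
DEFAULT_LENGTHS = {"cca": 15.0, "ica": 12.0, "eca": 10.0}
DEFAULT_TAPERS = {"cca": 0.10, "ica": 0.18, "eca": 0.12}
#: fraction of the CCA volume flow entering the internal carotid
DEFAULT_FLOW_SPLIT = {"ica": 0.65, "eca": 0.35}

WT_FLOOR_MM = 0.1


@dataclass
class BranchSpec:
    """One straight branch: an axis segment with a (linearly tapering) radius.

    ``radius`` is the radius at the junction end (s = 0); ``taper`` is the
    fractional reduction reached at the far end, so
    ``R(s) = radius * (1 - taper * s / length)``.  ``peak_velocity`` is the
    parabolic-profile peak at s = 0 in cm/s; along a tapering branch the
    peak scales as ``(R(0)/R(s))**2`` (volume-flow conservation).
    """

    name: str
    start: np.ndarray  # mm, junction end for daughters, junction end for CCA
    direction: np.ndarray  # unit vector, pointing away from the junction
    length: float  # mm
    radius: float  # mm at s = 0
    taper: float = 0.0
    peak_velocity: float = 0.0  # cm/s at s = 0

    @property
    def end(self) -> np.ndarray:
        return self.start + self.length * self.direction

    @property
    def min_radius(self) -> float:
        return self.radius * (1.0 - max(self.taper, 0.0))

    def radius_at(self, s: np.ndarray) -> np.ndarray:
        s = np.clip(s, 0.0, self.length)
        return self.radius * (1.0 - self.taper * s / self.length)

    def peak_velocity_at(self, s: np.ndarray) -> np.ndarray:
        """Flow-conserving parabolic peak along the branch [cm/s]."""
        return self.peak_velocity * (self.radius / self.radius_at(s)) ** 2

    def axial_radial(self, points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Axial coordinate (mm along axis from start) and radial distance."""
        rel = points - self.start
        s = rel @ self.direction
        radial = np.linalg.norm(rel - np.outer(s, self.direction), axis=1)
        return s, radial

    def sdf(self, points: np.ndarray) -> np.ndarray:
        """Signed distance to the capped (tapered) cylinder, negative inside.

        Exact for taper 0; for small tapers the radial term ignores the
        slant factor cos(atan(taper*radius/length)), an error below 0.1%
        for the tapers used here.
        """
        s, rho = self.axial_radial(points)
        dx = rho - self.radius_at(s)
        dy = np.maximum(-s, s - self.length)
        outside = np.hypot(np.maximum(dx, 0.0), np.maximum(dy, 0.0))
        inside = np.minimum(np.maximum(dx, dy), 0.0)
        return outside + inside

    def distance_to_axis_segment(self, points: np.ndarray) -> np.ndarray:
        s, rho = self.axial_radial(points)
        s_clamped = np.clip(s, 0.0, self.length)
        foot = self.start + np.outer(s_clamped, self.direction)
        return np.linalg.norm(points - foot, axis=1)


def _build_branches(
    radii: Dict[str, float],
    branch_angles: Dict[str, float],
    lengths: Dict[str, float],
    tapers: Dict[str, float],
) -> List[BranchSpec]:
    """Assemble branch specs; the junction sits at the origin."""
    branches = []
    for name, r in radii.items():
        if r <= 0:
            raise ValueError(f"branch {name!r} radius must be positive, got {r}")
        length = lengths[name]
        if length < 3.0 * r:
            raise ValueError(
                f"branch {name!r} length {length} mm is below 3x radius ({3 * r} mm)"
            )
        if name == "cca":
            # oriented away from the junction (at the origin), like daughters
            start, direction = np.zeros(3), np.array([0.0, 0.0, -1.0])
        else:
            ang = np.deg2rad(branch_angles[name])
            direction = np.array([np.sin(ang), 0.0, np.cos(ang)])
            start = np.zeros(3)
        branches.append(
            BranchSpec(name, start, direction, length, r, taper=tapers.get(name, 0.0))
        )
    return branches


def _assign_flow(
    branches: List[BranchSpec],
    peak_velocity: float,
    flow_split: Optional[Dict[str, float]] = None,
) -> None:
    """Set per-branch peak velocities by volume-flow conservation.

    ``peak_velocity`` is the CCA parabolic peak at the junction [cm/s];
    each daughter receives its ``flow_split`` fraction of the CCA volume
    flow, so its junction peak is ``f * v_cca * (R_cca/R_b)**2``.
    """
    split = dict(DEFAULT_FLOW_SPLIT if flow_split is None else flow_split)
    cca = next((b for b in branches if b.name == "cca"), None)
    daughters = [b for b in branches if b.name != "cca"]
    if cca is None:
        for b in branches:
            b.peak_velocity = peak_velocity
        return
    cca.peak_velocity = peak_velocity
    if daughters:
        total = sum(split.get(b.name, 0.0) for b in daughters)
        for b in daughters:
            f = split.get(b.name, 0.0) / total if total > 0 else 1.0 / len(daughters)
            b.peak_velocity = f * peak_velocity * (cca.radius / b.radius) ** 2


def _check_no_branch_overlap(branches: List[BranchSpec]) -> None:
    """Reject daughter-branch pairs that merge beyond the junction region."""
    daughters = [b for b in branches if b.name != "cca"]
    for i in range(len(daughters)):
        for j in range(i + 1, len(daughters)):
            a, b = daughters[i], daughters[j]
            gap = np.linalg.norm(a.end - b.end)
            ra = float(a.radius_at(np.array(a.length)))
            rb = float(b.radius_at(np.array(b.length)))
            if gap < ra + rb:
                raise ValueError(
                    f"branches {a.name!r} and {b.name!r} self-intersect at their "
                    f"outlets (end separation {gap:.2f} mm < sum of radii "
                    f"{ra + rb:.2f} mm); increase the angle between them"
                )


def _union_sdf(points: np.ndarray, branches: List[BranchSpec]) -> np.ndarray:
    return np.min(np.stack([b.sdf(points) for b in branches]), axis=0)


def _label_vertices(vertices: np.ndarray, branches: List[BranchSpec]) -> np.ndarray:
    """Nearest-branch labels, with a saddle region labelled 'bifurcation'."""
    sdfs = np.stack([b.sdf(vertices) for b in branches])
    nearest = np.argmin(sdfs, axis=0)
    labels = np.array([_BRANCH_CODE[branches[k].name] for k in nearest])
    if len(branches) > 1:
        max_r = max(b.radius for b in branches)
        junction = np.zeros(3)
        near_junction = np.linalg.norm(vertices - junction, axis=1) < 1.5 * max_r
        labels[near_junction] = BIFURCATION
    return labels


def _cap_mask(vertices: np.ndarray, branches: List[BranchSpec], pitch: float) -> np.ndarray:
    """Vertices on the flat end disks the closed surface necessarily has.

    A branch end is a free (capped) end when the surface actually
    terminates there, i.e. the region just beyond it is not interior to
    any other branch (the junction ends of a bifurcation are not caps).
    """
    mask = np.zeros(len(vertices), dtype=bool)
    for b in branches:
        s, rho = b.axial_radial(vertices)
        near_axis = rho < b.radius + pitch
        # outlet end (s = length) is always free
        mask |= (s > b.length - 1.3 * pitch) & near_axis
        # start end (s = 0): free unless buried inside another branch
        probe = b.start - 0.5 * b.radius * b.direction
        buried = any(
            other.sdf(probe[None, :])[0] < -0.25 * b.radius
            for other in branches
            if other is not b
        )
        if not buried:
            mask |= (s < 1.3 * pitch) & near_axis
    return mask


def generate_bifurcation_mesh(
    radii: Optional[Dict[str, float]] = None,
    branch_angles: Optional[Dict[str, float]] = None,
    jitter: float = 0.0,
    seed: int = 0,
    lengths: Optional[Dict[str, float]] = None,
    pitch: float = 0.7,
    tapers: Optional[Dict[str, float]] = None,
    return_branches: bool = False,
):
    """Triangulated carotid-bifurcation lumen surface.

    Parameters
    ----------
    radii : mapping branch name -> junction-end radius [mm]
        Any subset of {"cca", "ica", "eca"}; a single entry yields a
        straight tube.  Defaults to a realistic carotid geometry.
    branch_angles : mapping daughter name -> angle from the CCA axis [deg]
    jitter : float
        Fractional per-subject variability: radii and angles are scaled
        by independent ``1 + N(0, jitter)`` draws (clipped at 2 sigma to
        keep every subject's geometry physical).
    seed : int
        Seeds the jitter draws; the surface itself is deterministic.
    lengths : mapping branch name -> length [mm]; default carotid-like.
    pitch : float
        Marching-cubes voxel size [mm]; controls mesh resolution.
    tapers : mapping branch name -> fractional narrowing at the far end.
        Defaults to carotid-like tapers when ``radii`` is defaulted, and
        to untapered branches when radii are given explicitly.
    return_branches : bool
        Also return the (jittered) :class:`BranchSpec` list.

    Returns
    -------
    VesselMesh, or (VesselMesh, list[BranchSpec]) if ``return_branches``.
    """
    if tapers is None:
        tapers = dict(DEFAULT_TAPERS) if radii is None else {}
    radii = dict(DEFAULT_RADII if radii is None else radii)
    branch_angles = dict(DEFAULT_ANGLES if branch_angles is None else branch_angles)
    lengths = dict(DEFAULT_LENGTHS if lengths is None else lengths)
    lengths = {k: lengths.get(k, DEFAULT_LENGTHS.get(k, 4.0 * radii[k])) for k in radii}

    rng = np.random.default_rng(seed)
    if jitter > 0:
        for k in sorted(radii):
            z = float(np.clip(rng.standard_normal(), -2.0, 2.0))
            radii[k] = radii[k] * (1.0 + jitter * z)
        for k in sorted(branch_angles):
            if k in radii:
                z = float(np.clip(rng.standard_normal(), -2.0, 2.0))
                branch_angles[k] = branch_angles[k] * (1.0 + jitter * z)

    branches = _build_branches(radii, branch_angles, lengths, tapers)
    _check_no_branch_overlap(branches)

    lo = np.min([np.minimum(b.start, b.end) for b in branches], axis=0)
    hi = np.max([np.maximum(b.start, b.end) for b in branches], axis=0)
    max_r = max(b.radius for b in branches)
    lo -= max_r + 2.5 * pitch
    hi += max_r + 2.5 * pitch

    nx, ny, nz = (np.ceil((hi - lo) / pitch).astype(int) + 1)
    xs = lo[0] + pitch * np.arange(nx)
    ys = lo[1] + pitch * np.arange(ny)
    zs = lo[2] + pitch * np.arange(nz)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    vol = _union_sdf(grid, branches).reshape(nx, ny, nz)

    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(pitch,) * 3)
    verts = verts + lo

    import trimesh

    tm = trimesh.Trimesh(verts, faces, process=False)
    # keep the largest connected component (disjoint parameter sets would
    # otherwise yield floating shells)
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        tm = max(parts, key=lambda m: len(m.vertices))
    tm.fix_normals()
    verts, faces = np.asarray(tm.vertices), np.asarray(tm.faces)

    mesh = VesselMesh(
        vertices=verts,
        faces=faces,
        branch_label=_label_vertices(verts, branches),
        cap_mask=_cap_mask(verts, branches, pitch),
    )
    if return_branches:
        return mesh, branches
    return mesh


def _branch_weights_and_velocity(
    points: np.ndarray, branches: List[BranchSpec]
) -> np.ndarray:
    """Blended axial parabolic velocity field [cm/s] at mm points.

    Inside a single branch the profile is exactly
    ``v = v_peak(s) * (1 - rho^2/R(s)^2)`` along the branch axis, with
    the flow-conserving peak of :meth:`BranchSpec.peak_velocity_at`.
    Where branches overlap (the junction) the fields are blended by the
    smooth partition of unity ``w_b = max(0, 1 - rho/R)``; exactness is
    only claimed on single-branch segments.
    """
    v = np.zeros((len(points), 3))
    wsum = np.zeros(len(points))
    for b in branches:
        s, rho = b.axial_radial(points)
        r_local = b.radius_at(s)
        inside = (rho < r_local) & (s > 0.0) & (s < b.length)
        if not np.any(inside):
            continue
        w = np.zeros(len(points))
        w[inside] = np.maximum(0.0, 1.0 - rho[inside] / r_local[inside])
        mag = np.zeros(len(points))
        mag[inside] = b.peak_velocity_at(s[inside]) * (
            1.0 - (rho[inside] / r_local[inside]) ** 2
        )
        v += (w * mag)[:, None] * b.direction
        wsum += w
    nonzero = wsum > 1e-12
    v[nonzero] /= wsum[nonzero, None]
    return v


def generate_velocity_image(
    lumen: VesselMesh,
    peak_velocity: float = 60.0,
    voxel_mm: Sequence[float] = (0.5, 0.5, 0.5),
    noise_sd: float = 0.0,
    background_offset: Sequence[float] = (0.0, 0.0, 0.0),
    seed: int = 0,
    branches: Optional[List[BranchSpec]] = None,
    margin_mm: float = 4.0,
    flow_split: Optional[Dict[str, float]] = None,
) -> VelocityImage:
    """Steady 3-component velocity volume [cm/s] around a synthetic lumen.

    The axial velocity inside the lumen follows the per-branch parabolic
    profile (peaks set by volume-flow conservation from ``peak_velocity``
    at the CCA junction); outside it is zero.  A constant
    ``background_offset`` (one value per world component, emulating
    uncorrected phase offsets) and i.i.d. Gaussian noise of ``noise_sd``
    are added everywhere.

    ``branches`` are the generating branch specs; they are required
    because the analytic profile is defined by the axes, not the mesh.
    """
    if branches is None:
        raise ValueError("branch specs are required to evaluate the analytic profile")
    voxel = np.asarray(voxel_mm, dtype=float)
    min_r = min(b.min_radius for b in branches)
    if np.any(voxel > min_r / 3.0):
        raise ValueError(
            f"voxel size {voxel} mm too coarse: must be <= radius/3 = "
            f"{min_r / 3.0:.2f} mm so that >=3 samples fit along a radius"
        )
    _assign_flow(branches, peak_velocity, flow_split)

    lo = lumen.vertices.min(axis=0) - margin_mm
    hi = lumen.vertices.max(axis=0) + margin_mm
    dims = np.ceil((hi - lo) / voxel).astype(int) + 1
    affine = np.eye(4)
    affine[:3, :3] = np.diag(voxel)
    affine[:3, 3] = lo

    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    centers = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * voxel + lo

    data = _branch_weights_and_velocity(centers, branches)
    data = data.reshape(*dims, 3)
    data += np.asarray(background_offset, dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * rng.standard_normal(data.shape)
    return VelocityImage(data=data, affine=affine, corrected=False)


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    ``beta_true`` holds the ground-truth coefficients of the linear wall
    model ``WT = b0 + b1*WSS + b2*D + b3*WSS*D + eps`` with units
    (mm, mm/Pa, dimensionless, mm/(Pa*mm)).  Defaults emulate a cohort of
    20 elderly subjects with sub-millimetre walls negatively coupled to
    wall shear stress.
    """

    n_subjects: int = 20
    beta_true: Tuple[float, float, float, float] = (1.0, -0.15, 0.05, 0.01)
    noise_sd: float = 0.2  # mm, i.i.d. per-vertex wall-thickness noise
    geometry_variability: float = 0.1  # fractional radius/angle jitter
    peak_velocity: float = 60.0  # cm/s, matches a venc-60 acquisition
    viscosity: float = 3.2e-3  # Pa*s
    background_offset: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # cm/s
    seed: int = 0
    mesh_pitch: float = 0.7  # mm, marching-cubes resolution
    voxel_mm: Tuple[float, float, float] = (0.45, 0.45, 0.45)
    velocity_noise_sd: float = 0.0  # cm/s, measurement noise on velocities
    noise_smoothing: int = 0  # neighbour-averaging passes on the WT noise field
    radii: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    branch_angles: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ANGLES))
    lengths: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LENGTHS))
    tapers: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TAPERS))
    flow_split: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FLOW_SPLIT))

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.peak_velocity <= 0:
            raise ValueError("peak_velocity must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        beta = np.asarray(self.beta_true, dtype=float)
        if beta.shape != (4,):
            raise ValueError("beta_true must have 4 entries")


@dataclass
class SyntheticSubject:
    subject_id: str
    lumen: VesselMesh
    outer_wall: VesselMesh
    velocity: Optional[VelocityImage]
    truth_maps: Dict[str, ScalarMap]
    truth_beta: np.ndarray
    branches: List[BranchSpec]


def _smooth_vertex_field(mesh: VesselMesh, values: np.ndarray, passes: int) -> np.ndarray:
    """Neighbour-averaging smoothing of a per-vertex field (for spatially
    correlated noise); rescaled afterwards to preserve the sample SD."""
    from scipy.sparse import coo_matrix

    e = mesh.trimesh.edges_unique
    n = mesh.n_vertices
    rows = np.concatenate([e[:, 0], e[:, 1], np.arange(n)])
    cols = np.concatenate([e[:, 1], e[:, 0], np.arange(n)])
    w = np.ones(len(rows))
    adj = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    out = values.copy()
    for _ in range(passes):
        out = adj @ out / deg
    sd_in, sd_out = values.std(), out.std()
    if sd_out > 0:
        out *= sd_in / sd_out
    return out


def _truth_fields(
    points: np.ndarray, branches: List[BranchSpec], config: CohortConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Analytic WSS [Pa] and diameter [mm] at arbitrary mm points.

    WSS follows the Poiseuille closed form 2*mu*v_peak(s)/R(s) of the
    nearest branch at its local (tapered, flow-conserving) radius and
    peak velocity; diameter is twice the distance to the nearest branch
    axis, matching the nearest-centerline-point diameter definition.
    """
    _assign_flow(branches, config.peak_velocity, config.flow_split)
    sdfs = np.stack([b.sdf(points) for b in branches])
    nearest_branch = np.argmin(sdfs, axis=0)
    wss = np.empty(len(points))
    for k, b in enumerate(branches):
        sel = nearest_branch == k
        if not np.any(sel):
            continue
        s, _ = b.axial_radial(points[sel])
        wss[sel] = poiseuille_wss_pa(
            b.peak_velocity_at(s), b.radius_at(s), config.viscosity
        )
    axis_dist = np.min(
        np.stack([b.distance_to_axis_segment(points) for b in branches]), axis=0
    )
    return wss, 2.0 * axis_dist


def _truth_maps_for(
    lumen: VesselMesh,
    branches: List[BranchSpec],
    config: CohortConfig,
    noise_rng: np.random.Generator,
) -> Tuple[Dict[str, ScalarMap], np.ndarray]:
    """Analytic WSS and diameter plus the model-generated WT map."""
    wss, diameter = _truth_fields(lumen.vertices, branches, config)
    b0, b1, b2, b3 = config.beta_true
    wt_clean = b0 + b1 * wss + b2 * diameter + b3 * wss * diameter
    eps = config.noise_sd * noise_rng.standard_normal(lumen.n_vertices)
    if config.noise_smoothing > 0 and config.noise_sd > 0:
        eps = _smooth_vertex_field(lumen, eps, config.noise_smoothing)
    wt = wt_clean + eps
    nonphysical = np.mean(wt <= 0)
    if nonphysical > 0.20:
        warnings.warn(
            f"beta_true yields non-physical WT (<=0 before clipping) on "
            f"{100 * nonphysical:.1f}% of vertices",
            stacklevel=2,
        )
    wt = np.maximum(wt, WT_FLOOR_MM)

    maps = {
        "wss": ScalarMap(lumen, wss, "WSS"),
        "wt": ScalarMap(lumen, wt, "WT"),
        "diameter": ScalarMap(lumen, diameter, "D"),
    }
    return maps, wt, eps


def _offset_outer_wall(
    lumen: VesselMesh,
    branches: List[BranchSpec],
    config: CohortConfig,
    wt_vertex: np.ndarray,
    eps_vertex: np.ndarray,
    pitch: float,
) -> VesselMesh:
    """Outer wall as the level set ``distance_to_lumen(p) = WT(p)``.

    Offsetting lumen vertices along their normals makes the two daughter
    branches' outer sheets cross in the bifurcation crotch; extracting
    the offset as a level set instead merges them there — the physical
    picture of a shared adventitia — and guarantees the outer surface
    strictly encloses the lumen wherever WT > 0.  The per-vertex noise
    in WT is carried onto the level set via nearest-lumen-vertex lookup.
    """
    from scipy.spatial import cKDTree

    b0, b1, b2, b3 = config.beta_true
    tree = cKDTree(lumen.vertices)
    wt_max = float(wt_vertex.max()) + 0.5
    grid_pitch = 0.6 * pitch
    lo = lumen.vertices.min(axis=0) - (wt_max + 2.5 * grid_pitch)
    hi = lumen.vertices.max(axis=0) + (wt_max + 2.5 * grid_pitch)
    nx, ny, nz = (np.ceil((hi - lo) / grid_pitch).astype(int) + 1)
    xs = lo[0] + grid_pitch * np.arange(nx)
    ys = lo[1] + grid_pitch * np.arange(ny)
    zs = lo[2] + grid_pitch * np.arange(nz)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)

    wss_g, d_g = _truth_fields(grid, branches, config)
    wt_g = b0 + b1 * wss_g + b2 * d_g + b3 * wss_g * d_g
    # carry the vertex noise onto the grid by inverse-distance weighting of
    # the 4 nearest lumen vertices (smoother than nearest-vertex lookup)
    dist_v, idx_v = tree.query(grid, k=4)
    w = 1.0 / np.maximum(dist_v, 1e-6)
    wt_g = wt_g + np.sum(w * eps_vertex[idx_v], axis=1) / np.sum(w, axis=1)
    # surface floor: the physical 0.1 mm floor, widened to a fraction of the
    # grid pitch so linear interpolation of the level set cannot cross the
    # lumen surface
    wt_g = np.maximum(wt_g, max(WT_FLOOR_MM, 0.5 * grid_pitch))
    level = (_union_sdf(grid, branches) - wt_g).reshape(nx, ny, nz)

    verts, faces, _, _ = measure.marching_cubes(
        level, level=0.0, spacing=(grid_pitch,) * 3
    )
    verts = verts + lo

    import trimesh

    tm = trimesh.Trimesh(verts, faces, process=False)
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        tm = max(parts, key=lambda m: len(m.vertices))
    tm.fix_normals()
    verts, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
    return VesselMesh(
        vertices=verts,
        faces=faces,
        branch_label=_label_vertices(verts, branches),
        cap_mask=_cap_mask(verts, branches, pitch),
    )


def generate_cohort(config: CohortConfig, with_velocity: bool = True) -> List[SyntheticSubject]:
    """Generate a reproducible cohort of synthetic subjects.

    With ``with_velocity=False`` the velocity volume is skipped, which is
    much cheaper when only the geometric/ground-truth maps are needed.
    """
    master = np.random.SeedSequence(config.seed)
    subject_seqs = master.spawn(config.n_subjects)
    subjects = []
    for i, seq in enumerate(subject_seqs):
        geom_seq, wt_seq, vel_seq = seq.spawn(3)
        geom_seed = int(geom_seq.generate_state(1)[0] % (2**31))
        lumen, branches = generate_bifurcation_mesh(
            radii=config.radii,
            branch_angles=config.branch_angles,
            jitter=config.geometry_variability,
            seed=geom_seed,
            lengths=config.lengths,
            pitch=config.mesh_pitch,
            tapers=config.tapers,
            return_branches=True,
        )
        maps, wt, eps = _truth_maps_for(
            lumen, branches, config, np.random.default_rng(wt_seq)
        )
        outer = _offset_outer_wall(lumen, branches, config, wt, eps, config.mesh_pitch)
        velocity = None
        if with_velocity:
            vel_seed = int(vel_seq.generate_state(1)[0] % (2**31))
            velocity = generate_velocity_image(
                lumen,
                peak_velocity=config.peak_velocity,
                voxel_mm=config.voxel_mm,
                noise_sd=config.velocity_noise_sd,
                background_offset=config.background_offset,
                seed=vel_seed,
                branches=branches,
                flow_split=config.flow_split,
            )
        subjects.append(
            SyntheticSubject(
                subject_id=f"subject_{i:03d}",
                lumen=lumen,
                outer_wall=outer,
                velocity=velocity,
                truth_maps=maps,
                truth_beta=np.asarray(config.beta_true, dtype=float),
                branches=branches,
            )
        )
    return subjects
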