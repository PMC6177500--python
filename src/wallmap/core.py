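"""Core domain containers shared by every stage of the analysis.

All geometry lives in a single right-handed world frame in millimetres;
velocities are stored in cm/s (the native scale of phase-contrast MRI
with a typical venc of 60 cm/s) and wall shear stress in pascal.  Unit
conversions are centralised in :mod:`wallmap.units`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import trimesh

# Integer branch codes carried per vertex.  The common carotid (CCA)
# bifurcates into the internal (ICA) and external (ECA) carotid; the
# saddle region between them is labelled separately.
CCA, ICA, ECA, BIFURCATION = 0, 1, 2, 3
BRANCH_NAMES = {CCA: "CCA", ICA: "ICA", ECA: "ECA", BIFURCATION: "bifurcation"}
BRANCH_CODES = {v: k for k, v in BRANCH_NAMES.items()}


@dataclass
class VesselMesh:
    """Triangulated vessel wall surface with per-vertex branch labels.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array
        Triangles referencing ``vertices``; outward orientation.
    branch_label : (n,) int array
        One of ``CCA``, ``ICA``, ``ECA``, ``BIFURCATION`` per vertex.
    cap_mask : (n,) bool array, optional
        True for vertices on artificial inlet/outlet cap disks (present
        on closed synthetic meshes; all-False when unknown).
    """

    vertices: np.ndarray
    faces: np.ndarray
    branch_label: np.ndarray
    cap_mask: Optional[np.ndarray] = None
    _tm: Optional[trimesh.Trimesh] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.branch_label = np.asarray(self.branch_label, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face references a vertex that does not exist")
        if len(self.branch_label) != len(self.vertices):
            raise ValueError("one branch label per vertex required")
        if self.cap_mask is None:
            self.cap_mask = np.zeros(len(self.vertices), dtype=bool)
        else:
            self.cap_mask = np.asarray(self.cap_mask, dtype=bool)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def trimesh(self) -> trimesh.Trimesh:
        """Lazily built :class:`trimesh.Trimesh` view (no vertex merging)."""
        if self._tm is None or len(self._tm.vertices) != len(self.vertices):
            self._tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
        return self._tm

    @property
    def outward_normals(self) -> np.ndarray:
        """Unit vertex normals pointing away from the enclosed lumen."""
        return np.asarray(self.trimesh.vertex_normals, dtype=float)

    @property
    def inward_normals(self) -> np.ndarray:
        """Unit vertex normals pointing into the lumen."""
        return -self.outward_normals

    @property
    def mean_edge_length(self) -> float:
        return float(self.trimesh.edges_unique_length.mean())

    def copy_with_vertices(self, vertices: np.ndarray) -> "VesselMesh":
        return VesselMesh(
            vertices=np.array(vertices, dtype=float),
            faces=self.faces.copy(),
            branch_label=self.branch_label.copy(),
            cap_mask=self.cap_mask.copy(),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "VesselMesh":
        """Rigidly transformed copy: ``v -> v @ R.T + t``."""
        return self.copy_with_vertices(self.vertices @ np.asarray(rotation).T + translation)


# Map kinds and the units they are reported in.
MAP_UNITS = {
    "WT": "mm",
    "WSS": "Pa",
    "D": "mm",
    "residual": "mm",
    "predicted_WT": "mm",
}


@dataclass
class ScalarMap:
    """One per-vertex scalar quantity bound to a mesh.

    Missing vertices (e.g. excluded from WSS estimation because a sample
    fell outside the image) carry NaN and are propagated through every
    downstream statistic.
    """

    mesh: VesselMesh
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in MAP_UNITS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if len(self.values) != self.mesh.n_vertices:
            raise ValueError("one value per mesh vertex required")
        finite = self.values[np.isfinite(self.values)]
        if self.kind in ("WT", "D") and finite.size and finite.min() <= 0:
            raise ValueError(f"{self.kind} map must be strictly positive")
        if self.kind == "WSS" and finite.size and finite.min() < 0:
            raise ValueError("WSS magnitude map must be non-negative")

    @property
    def units(self) -> str:
        return MAP_UNITS[self.kind]

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class Centerline:
    """Per-branch lumen centerlines with maximal inscribed-sphere radii.

    ``points[name]`` is an ordered (k, 3) polyline in mm running from the
    CCA inlet towards the branch outlet; ``radius[name]`` holds the local
    inscribed radius at each point.  Daughter-branch paths share the CCA
    trajectory through the bifurcation.
    """

    points: Dict[str, np.ndarray]
    radius: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, pts in self.points.items():
            pts = np.asarray(pts, dtype=float)
            self.points[name] = pts
            self.radius[name] = np.asarray(self.radius[name], dtype=float)
            if len(pts) < 2:
                raise ValueError(f"branch {name!r} needs at least 2 centerline points")
            if len(self.radius[name]) != len(pts):
                raise ValueError("one radius per centerline point required")
            if np.any(self.radius[name] <= 0):
                raise ValueError("inscribed radii must be positive")

    def all_points(self) -> np.ndarray:
        return np.vstack([self.points[k] for k in sorted(self.points)])

    def all_radii(self) -> np.ndarray:
        return np.concatenate([self.radius[k] for k in sorted(self.points)])


@dataclass
class VelocityImage:
    """3-component velocity volume on a regular grid.

    ``data`` has shape (nx, ny, nz, 3) with components in cm/s expressed
    in world (x, y, z) axes; ``affine`` maps voxel indices to world mm
    coordinates, as in NIfTI.
    """

    data: np.ndarray
    affine: np.ndarray
    corrected: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError("velocity data must be (nx, ny, nz, 3)")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("velocity data must be finite")

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        pts = np.atleast_2d(points_mm)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
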