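"""Shared cohort geometry and vertex-wise map averaging.

Cohort averaging proceeds in the three canonical steps: (1) build a
shared geometry — here the first subject's lumen mesh, with every other
subject rigidly aligned to it (bifurcation-landmark + branch-direction
initialisation, then iterative-closest-point refinement); (2) resample
each subject's per-vertex maps onto the shared vertices via
nearest-vertex correspondence with a distance gate; (3) average maps
vertex-wise over arbitrary subject multisets (with repetition, as the
subject-level bootstrap requires).

Missing-data policy: gated-out atlas vertices are missing for that
subject; averaging is available-case per vertex with the contributing
count recorded; downstream statistics default to "complete" vertices
covered by every subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import BIFURCATION, CCA, ICA, ScalarMap, VesselMesh

__all__ = [
    "SharedGeometry",
    "CohortMapSet",
    "build_shared_geometry",
    "map_to_shared",
    "average_maps",
    "build_cohort_mapset",
]

QUANTITIES = ("WT", "WSS", "D")


def _landmark_and_frame(mesh: VesselMesh) -> Tuple[np.ndarray, np.ndarray]:
    """Bifurcation landmark and an orthonormal branch frame.

    The landmark is the centroid of the bifurcation-labelled vertices
    (mesh centroid for unbranched meshes).  The frame's first axis is
    the CCA direction, the second the ICA direction orthogonalised
    against it, the third their cross product.
    """
    labels = mesh.branch_label
    bif = labels == BIFURCATION
    if bif.sum() >= 10:
        landmark = mesh.vertices[bif].mean(axis=0)
    else:
        landmark = mesh.vertices.mean(axis=0)

    def direction(code: int) -> np.ndarray:
        pts = mesh.vertices[labels == code]
        if len(pts) < 30:
            return np.zeros(3)
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        d = vt[0]
        if (pts.mean(axis=0) - landmark) @ d < 0:
            d = -d
        return d

    e1 = direction(CCA)
    e2 = direction(ICA)
    if np.linalg.norm(e1) == 0:
        raise ValueError("mesh lacks CCA branch labels; cannot build alignment frame")
    if np.linalg.norm(e2) == 0:
        # unbranched mesh: any frame completing the CCA axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(e1 @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e2 = helper
    e2 = e2 - (e2 @ e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return landmark, np.column_stack([e1, e2, e3])


def _kabsch(src: np.ndarray, dst: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform R, t with dst ~ src @ R.T + t."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, cd - r @ cs


def _icp_refine(
    src: np.ndarray,
    target_tree: cKDTree,
    target_pts: np.ndarray,
    r0: np.ndarray,
    t0: np.ndarray,
    iterations: int = 20,
    sample: int = 800,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Point-to-point ICP starting from (r0, t0); returns (R, t, rms)."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(src), size=min(sample, len(src)), replace=False)
    pts = src[idx]
    r, t = r0.copy(), t0.copy()
    rms = np.inf
    for _ in range(iterations):
        moved = pts @ r.T + t
        d, j = target_tree.query(moved)
        new_rms = float(np.sqrt(np.mean(d**2)))
        r, t = _kabsch(pts, target_pts[j])
        if abs(rms - new_rms) < 1e-8:
            rms = new_rms
            break
        rms = new_rms
    return r, t, rms


@dataclass
class SharedGeometry:
    """Atlas mesh plus per-subject vertex correspondences.

    ``correspondence[s, a]`` is the source-vertex index in subject ``s``
    matched to atlas vertex ``a`` (weight 1), or -1 where the match was
    farther than ``gate_mm``; ``coverage`` marks valid matches.
    """

    atlas: VesselMesh
    correspondence: np.ndarray  # (n_subjects, n_atlas) int
    coverage: np.ndarray  # (n_subjects, n_atlas) bool
    transforms: List[Tuple[np.ndarray, np.ndarray]]  # subject -> atlas (R, t)
    gate_mm: float
    alignment_rms: np.ndarray  # (n_subjects,)

    @property
    def n_subjects(self) -> int:
        return self.correspondence.shape[0]


def build_shared_geometry(
    lumens: Sequence[VesselMesh],
    icp_iterations: int = 20,
    rms_warn_mm: float = 2.0,
    coverage_warn: float = 0.80,
    seed: int = 0,
) -> SharedGeometry:
    """Register all subjects to the first subject's mesh (the atlas).

    Initial alignment translates each subject's bifurcation landmark
    onto the atlas landmark and rotates its CCA/ICA branch frame onto
    the atlas frame; ICP refines.  Correspondences are nearest aligned
    source vertices within a gate of twice the atlas mean edge length.
    """
    if len(lumens) < 2:
        raise ValueError("a shared geometry needs at least 2 meshes")
    atlas = lumens[0]
    gate = 2.0 * atlas.mean_edge_length
    lm_a, frame_a = _landmark_and_frame(atlas)
    atlas_tree = cKDTree(atlas.vertices)

    n_atlas = atlas.n_vertices
    corr = np.full((len(lumens), n_atlas), -1, dtype=np.int64)
    cov = np.zeros((len(lumens), n_atlas), dtype=bool)
    transforms = []
    rms_all = np.zeros(len(lumens))
    for s, mesh in enumerate(lumens):
        if s == 0:
            r, t = np.eye(3), np.zeros(3)
            rms = 0.0
        else:
            lm_s, frame_s = _landmark_and_frame(mesh)
            r0 = frame_a @ frame_s.T
            t0 = lm_a - r0 @ lm_s
            r, t, rms = _icp_refine(
                mesh.vertices, atlas_tree, atlas.vertices, r0, t0,
                iterations=icp_iterations, seed=seed + s,
            )
            if rms > rms_warn_mm:
                warnings.warn(
                    f"subject {s}: alignment RMS {rms:.2f} mm exceeds "
                    f"{rms_warn_mm} mm", stacklevel=2,
                )
        transforms.append((r, t))
        rms_all[s] = rms
        aligned = mesh.vertices @ r.T + t
        tree = cKDTree(aligned)
        dist, idx = tree.query(atlas.vertices)
        ok = dist <= gate
        corr[s, ok] = idx[ok]
        cov[s] = ok
        if ok.mean() < coverage_warn:
            warnings.warn(
                f"subject {s}: atlas coverage {100 * ok.mean():.1f}% below "
                f"{100 * coverage_warn:.0f}%", stacklevel=2,
            )
    return SharedGeometry(
        atlas=atlas,
        correspondence=corr,
        coverage=cov,
        transforms=transforms,
        gate_mm=gate,
        alignment_rms=rms_all,
    )


def map_to_shared(
    scalar_map: ScalarMap, shared: SharedGeometry, subject_index: int
) -> np.ndarray:
    """Resample one subject's per-vertex map onto the atlas vertices.

    Returns a vector over atlas vertices with NaN where the subject has
    no gated correspondence or the source value is missing.
    """
    if not 0 <= subject_index < shared.n_subjects:
        raise ValueError(f"subject index {subject_index} not in shared geometry")
    idx = shared.correspondence[subject_index]
    out = np.full(shared.atlas.n_vertices, np.nan)
    valid = shared.coverage[subject_index]
    out[valid] = scalar_map.values[idx[valid]]
    return out


@dataclass
class CohortMapSet:
    """Subjects x atlas-vertices matrices for each quantity.

    ``matrices[q][s, a]`` is subject ``s``'s value of quantity ``q`` at
    atlas vertex ``a`` (NaN = missing).  ``shared`` may be None for map
    matrices constructed without a geometric atlas (e.g. simulation
    studies on abstract vertex sets).
    """

    shared: Optional[SharedGeometry]
    matrices: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.matrices.values()}
        if len(shapes) > 1:
            raise ValueError("all quantity matrices must share a shape")

    @property
    def n_subjects(self) -> int:
        return next(iter(self.matrices.values())).shape[0]

    @property
    def n_vertices(self) -> int:
        return next(iter(self.matrices.values())).shape[1]

    def complete_vertices(self, quantities: Optional[Sequence[str]] = None) -> np.ndarray:
        """Atlas vertices with finite values for all subjects and quantities."""
        if quantities is None:
            quantities = [q for q in QUANTITIES if q in self.matrices]
        mask = np.ones(self.n_vertices, dtype=bool)
        for q in quantities:
            mask &= np.all(np.isfinite(self.matrices[q]), axis=0)
        return mask

    def save_npz(self, path) -> None:
        extra = {}
        if self.shared is not None:
            extra = {
                "coverage": self.shared.coverage,
                "correspondence": self.shared.correspondence,
            }
        np.savez_compressed(
            path, **{f"map_{q}": m for q, m in self.matrices.items()}, **extra
        )


def build_cohort_mapset(
    shared: SharedGeometry, per_subject_maps: Sequence[Dict[str, ScalarMap]]
) -> CohortMapSet:
    """Resample every subject's maps onto the atlas and stack them."""
    if len(per_subject_maps) != shared.n_subjects:
        raise ValueError("one map dict per subject required")
    matrices = {}
    for q in per_subject_maps[0]:
        rows = [
            map_to_shared(maps[q], shared, s) for s, maps in enumerate(per_subject_maps)
        ]
        matrices[q] = np.vstack(rows)
    return CohortMapSet(shared=shared, matrices=matrices)


def average_maps(
    mapset: CohortMapSet, subject_multiset: Sequence[int], quantity: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Vertex-wise mean over a subject multiset (with repetition).

    Returns ``(mean, n_contributing)`` per atlas vertex; the mean is NaN
    where no entry of the multiset has a valid value (available-case
    averaging).
    """
    idx = np.asarray(subject_multiset, dtype=int)
    if idx.size == 0:
        raise ValueError("empty subject multiset")
    if idx.min() < 0 or idx.max() >= mapset.n_subjects:
        raise ValueError("subject index out of range")
    rows = mapset.matrices[quantity][idx]
    count = np.sum(np.isfinite(rows), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(rows, axis=0)
    return mean, count
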