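"""File formats: labeled meshes (PLY/OBJ/STL), maps (CSV), velocity
volumes (NIfTI), centerlines (JSON) and cohort map sets (NPZ).

Vessel meshes are written as binary little-endian PLY with the branch
label and cap flag as integer per-vertex properties (plus any scalar
maps passed as extra float properties).  Reading falls back to trimesh
for foreign files without those properties.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .core import Centerline, ScalarMap, VelocityImage, VesselMesh

__all__ = [
    "write_mesh_ply",
    "read_mesh",
    "write_map_csv",
    "read_map_csv",
    "write_velocity_nifti",
    "read_velocity_nifti",
    "write_centerline_json",
    "read_centerline_json",
]


def write_mesh_ply(
    mesh: VesselMesh, path, scalar_maps: Optional[Dict[str, ScalarMap]] = None
) -> None:
    """Binary little-endian PLY with per-vertex branch/cap properties."""
    path = Path(path)
    extra = scalar_maps or {}
    header = [
        "ply",
        "format binary_little_endian 1.0",
        f"element vertex {mesh.n_vertices}",
        "property float64 x",
        "property float64 y",
        "property float64 z",
        "property int32 branch",
        "property uint8 cap",
    ]
    for name in extra:
        header.append(f"property float64 {name}")
    header += [
        f"element face {len(mesh.faces)}",
        "property list uint8 int32 vertex_indices",
        "end_header",
    ]
    vdtype = [("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("branch", "<i4"), ("cap", "u1")]
    vdtype += [(name, "<f8") for name in extra]
    vdata = np.empty(mesh.n_vertices, dtype=vdtype)
    vdata["x"], vdata["y"], vdata["z"] = mesh.vertices.T
    vdata["branch"] = mesh.branch_label
    vdata["cap"] = mesh.cap_mask.astype(np.uint8)
    for name, m in extra.items():
        vdata[name] = m.values
    fdata = np.empty(len(mesh.faces), dtype=[("n", "u1"), ("idx", "<i4", (3,))])
    fdata["n"] = 3
    fdata["idx"] = mesh.faces
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(vdata.tobytes())
        fh.write(fdata.tobytes())


def _read_labeled_ply(path: Path) -> Optional[VesselMesh]:
    """Read a PLY written by :func:`write_mesh_ply`; None if foreign."""
    with open(path, "rb") as fh:
        header_lines = []
        while True:
            line = fh.readline().decode("ascii", errors="replace").strip()
            header_lines.append(line)
            if line == "end_header":
                break
            if len(header_lines) > 100:
                return None
        if header_lines[1] != "format binary_little_endian 1.0":
            return None
        props = [ln.split()[-1] for ln in header_lines if ln.startswith("property ") and "list" not in ln]
        if props[:5] != ["x", "y", "z", "branch", "cap"]:
            return None
        n_vert = int(next(ln.split()[-1] for ln in header_lines if ln.startswith("element vertex")))
        n_face = int(next(ln.split()[-1] for ln in header_lines if ln.startswith("element face")))
        vdtype = [("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("branch", "<i4"), ("cap", "u1")]
        vdtype += [(name, "<f8") for name in props[5:]]
        vdata = np.frombuffer(fh.read(np.dtype(vdtype).itemsize * n_vert), dtype=vdtype)
        fdtype = [("n", "u1"), ("idx", "<i4", (3,))]
        fdata = np.frombuffer(fh.read(np.dtype(fdtype).itemsize * n_face), dtype=fdtype)
    vertices = np.column_stack([vdata["x"], vdata["y"], vdata["z"]])
    return VesselMesh(
        vertices=vertices,
        faces=np.array(fdata["idx"]),
        branch_label=np.array(vdata["branch"], dtype=np.int64),
        cap_mask=vdata["cap"].astype(bool),
    )


def write_mesh_obj(mesh: VesselMesh, path) -> None:
    """Plain OBJ export (geometry only; labels live in the PLY format)."""
    mesh.trimesh.export(Path(path))


def read_mesh(path) -> VesselMesh:
    """Read PLY/OBJ/STL; labels default to a single branch for foreign files."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        mesh = _read_labeled_ply(path)
        if mesh is not None:
            return mesh
    tm = trimesh.load(path, process=False, force="mesh")
    return VesselMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
        branch_label=np.zeros(len(tm.vertices), dtype=np.int64),
    )


def write_map_csv(scalar_map: ScalarMap, path) -> None:
    pd.DataFrame(
        {"vertex_id": np.arange(len(scalar_map.values)), "value": scalar_map.values}
    ).to_csv(path, index=False)


def read_map_csv(path, mesh: VesselMesh, kind: str) -> ScalarMap:
    df = pd.read_csv(path)
    values = np.full(mesh.n_vertices, np.nan)
    values[df["vertex_id"].to_numpy()] = df["value"].to_numpy()
    return ScalarMap(mesh, values, kind)


def write_velocity_nifti(img: VelocityImage, path) -> None:
    """4D NIfTI (x, y, z, component), affine in mm, values in cm/s."""
    nib.Nifti1Image(img.data.astype(np.float32), img.affine).to_filename(str(path))


def read_velocity_nifti(path, corrected: bool = False) -> VelocityImage:
    ni = nib.load(str(path))
    return VelocityImage(
        data=np.asarray(ni.dataobj, dtype=float),
        affine=np.asarray(ni.affine, dtype=float),
        corrected=corrected,
    )


def write_centerline_json(cl: Centerline, path) -> None:
    payload = {
        name: {
            "points_mm": cl.points[name].tolist(),
            "inscribed_radius_mm": cl.radius[name].tolist(),
        }
        for name in cl.points
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_centerline_json(path) -> Centerline:
    payload = json.loads(Path(path).read_text())
    return Centerline(
        points={k: np.asarray(v["points_mm"]) for k, v in payload.items()},
        radius={k: np.asarray(v["inscribed_radius_mm"]) for k, v in payload.items()},
    )
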