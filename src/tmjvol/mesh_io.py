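"""STL and PLY mesh I/O.

STL (ASCII and binary) and ASCII PLY are enough to exchange watertight bone
surfaces with every mainstream mesh tool.  STL carries no unit metadata, so
readers accept a ``units_scale`` factor (default 1.0 = millimetres).
"""
from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np

from .config import UNITS_SCALE
from .mesh import TriangleMesh

__all__ = ["read_mesh", "write_mesh", "read_stl", "write_stl", "read_ply", "write_ply"]


def _dedupe(points: np.ndarray) -> TriangleMesh:
    """Weld exactly-coincident STL facet vertices into an indexed mesh."""
    verts, inverse = np.unique(points.reshape(-1, 3), axis=0, return_inverse=True)
    return TriangleMesh(verts, inverse.reshape(-1, 3))


def _watertight_report(mesh: TriangleMesh, path):
    n_open = mesh.open_edge_count
    if n_open:
        warnings.warn(
            f"{path}: mesh is not watertight ({n_open} open/non-manifold edges); "
            "volume computations on it will fail",
            stacklevel=3,
        )


def read_stl(path, units_scale: float = UNITS_SCALE) -> TriangleMesh:
    """Read an STL file, auto-detecting ASCII vs binary."""
    path = Path(path)
    raw = path.read_bytes()
    is_ascii = raw[:5] == b"solid" and b"facet" in raw[:1000]
    if is_ascii:
        pts = []
        for line in raw.decode("ascii", errors="replace").splitlines():
            parts = line.split()
            if len(parts) == 4 and parts[0] == "vertex":
                pts.append([float(x) for x in parts[1:]])
        points = np.asarray(pts, dtype=float)
        if len(points) == 0 or len(points) % 3:
            raise ValueError(f"{path}: malformed ASCII STL")
    else:
        if len(raw) < 84:
            raise ValueError(f"{path}: truncated binary STL")
        (n_tri,) = struct.unpack_from("<I", raw, 80)
        expected = 84 + 50 * n_tri
        if len(raw) < expected:
            raise ValueError(f"{path}: binary STL declares {n_tri} facets but file is short")
        data = np.frombuffer(raw, dtype=np.uint8, count=50 * n_tri, offset=84)
        facets = data.reshape(n_tri, 50)[:, :48].copy().view("<f4").reshape(n_tri, 4, 3)
        points = facets[:, 1:, :].astype(float).reshape(-1, 3)
    mesh = _dedupe(points * units_scale)
    _watertight_report(mesh, path)
    return mesh


def write_stl(mesh: TriangleMesh, path, binary: bool = False):
    """Write an STL file (ASCII by default; text-friendly)."""
    path = Path(path)
    tri = mesh.vertices[mesh.faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(n, axis=1)
    n = np.where(norms[:, None] > 0, n / np.where(norms[:, None] > 0, norms[:, None], 1.0), 0.0)
    if binary:
        with open(path, "wb") as f:
            f.write(b"\x00" * 80)
            f.write(struct.pack("<I", len(tri)))
            rec = np.zeros((len(tri), 50), dtype=np.uint8)
            block = np.ascontiguousarray(
                np.concatenate([n[:, None, :], tri], axis=1).astype("<f4")
            ).reshape(len(tri), 12)
            rec[:, :48] = block.view(np.uint8).reshape(len(tri), 48)
            f.write(rec.tobytes())
    else:
        with open(path, "w") as f:
            f.write("solid tmjvol\n")
            for nv, t in zip(n, tri):
                f.write(f"  facet normal {nv[0]:.9e} {nv[1]:.9e} {nv[2]:.9e}\n")
                f.write("    outer loop\n")
                for v in t:
                    f.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                f.write("    endloop\n  endfacet\n")
            f.write("endsolid tmjvol\n")


def read_ply(path, units_scale: float = UNITS_SCALE) -> TriangleMesh:
    """Read an ASCII PLY file with vertex x/y/z and triangular faces."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    n_vert = n_face = None
    props = []
    in_vertex = False
    i = 1
    fmt = None
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            in_vertex = parts[1] == "vertex"
            if in_vertex:
                n_vert = int(parts[2])
            elif parts[1] == "face":
                n_face = int(parts[2])
        elif parts[0] == "property" and in_vertex:
            props.append(parts[-1])
        elif parts[0] == "end_header":
            break
    if fmt != "ascii":
        raise ValueError(f"{path}: only ASCII PLY is supported")
    if n_vert is None or n_face is None:
        raise ValueError(f"{path}: missing vertex/face elements")
    ix, iy, iz = props.index("x"), props.index("y"), props.index("z")
    verts = np.empty((n_vert, 3))
    for v in range(n_vert):
        parts = lines[i + v].split()
        verts[v] = [float(parts[ix]), float(parts[iy]), float(parts[iz])]
    faces = []
    for fline in lines[i + n_vert : i + n_vert + n_face]:
        parts = [int(x) for x in fline.split()]
        if parts[0] != 3:
            raise ValueError(f"{path}: non-triangular face with {parts[0]} vertices")
        faces.append(parts[1:4])
    mesh = TriangleMesh(verts * units_scale, np.asarray(faces))
    _watertight_report(mesh, path)
    return mesh


def write_ply(mesh: TriangleMesh, path):
    """Write an ASCII PLY file."""
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write(f"element vertex {len(mesh.vertices)}\n")
        f.write("property double x\nproperty double y\nproperty double z\n")
        f.write(f"element face {len(mesh.faces)}\n")
        f.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            f.write(f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}\n")
        for t in mesh.faces:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_mesh(path, units_scale: float = UNITS_SCALE) -> TriangleMesh:
    """Read a mesh by file extension (.stl or .ply)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".stl":
        return read_stl(path, units_scale)
    if suffix == ".ply":
        return read_ply(path, units_scale)
    raise ValueError(f"unsupported mesh format: {suffix!r} (use .stl or .ply)")


def write_mesh(mesh: TriangleMesh, path, **kwargs):
    """Write a mesh by file extension (.stl or .ply)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".stl":
        return write_stl(mesh, path, **kwargs)
    if suffix == ".ply":
        return write_ply(mesh, path)
    raise ValueError(f"unsupported mesh format: {suffix!r} (use .stl or .ply)")
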