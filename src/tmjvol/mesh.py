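"""Triangle meshes, exact volumes, and voxel occupancy.

A :class:`TriangleMesh` is the stand-in for a reconstructed 3D bone model.
Volumes are computed two ways: exactly, by the divergence theorem on a
watertight mesh, and discretely, by a voxel :class:`OccupancyGrid` whose
inside test is ray-casting parity along a fixed, slightly skewed direction
(deterministic and robust to axis-aligned faces).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RAY_DIRECTION
from .geometry import RigidTransform

__all__ = [
    "TopologyError",
    "TriangleMesh",
    "OccupancyGrid",
    "mesh_volume",
    "contains",
    "voxelize",
    "box_mesh",
    "icosphere",
    "ellipsoid_mesh",
]


class TopologyError(ValueError):
    """Mesh topology unsuitable for volume computation (open/non-manifold)."""

    def __init__(self, message: str, open_edge_count: int = 0):
        super().__init__(message)
        self.open_edge_count = open_edge_count


@dataclass
class TriangleMesh:
    """Indexed triangle surface in mm.

    ``vertices``: (n, 3) float array; ``faces``: (m, 3) int array of vertex
    indices, counter-clockwise when viewed from outside for an
    outward-oriented mesh.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        self.faces = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    # -- topology ----------------------------------------------------------

    def _edge_counts(self):
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        und = np.sort(e, axis=1)
        _, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
        return e, counts, inverse

    @property
    def open_edge_count(self) -> int:
        if len(self.faces) == 0:
            return 0
        _, counts, _ = self._edge_counts()
        return int(np.count_nonzero(counts != 2))

    @property
    def is_watertight(self) -> bool:
        return len(self.faces) > 0 and self.open_edge_count == 0

    @property
    def is_oriented(self) -> bool:
        """True when every edge is used once in each direction."""
        if len(self.faces) == 0:
            return False
        e, counts, _ = self._edge_counts()
        if np.any(counts != 2):
            return False
        _, dcounts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(dcounts == 1))

    def require_watertight(self, context: str = "volume computation"):
        n_open = self.open_edge_count
        if len(self.faces) == 0 or n_open:
            raise TopologyError(
                f"mesh is not watertight ({n_open} open/non-manifold edges); "
                f"cannot proceed with {context}",
                open_edge_count=n_open,
            )

    # -- metrics -----------------------------------------------------------

    @property
    def bounds(self):
        """(min_corner, max_corner) of the axis-aligned bounding box."""
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    @property
    def area(self) -> float:
        tri = self.vertices[self.faces]
        c = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(np.linalg.norm(c, axis=1).sum() / 2.0)

    def transformed(self, T: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(T.apply(self.vertices), self.faces.copy())


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (mm^3) of a watertight mesh via the divergence theorem.

    Signed tetrahedra against the origin; orientation is normalized so the
    result is always positive.
    """
    mesh.require_watertight()
    tri = mesh.vertices[mesh.faces]
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    return float(abs(signed))


def contains(mesh: TriangleMesh, points, direction=RAY_DIRECTION, chunk: int = 256):
    """Ray-parity inside test for point(s) against a watertight mesh.

    A point is inside iff a ray along ``direction`` crosses the surface an
    odd number of times.  Points are processed in z-sorted chunks with
    triangle pre-selection on the z band, which keeps the dense
    Moller-Trumbore evaluation small.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    single = np.asarray(points).ndim == 1
    mesh.require_watertight("point containment")

    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)

    tri = mesh.vertices[mesh.faces]
    v0 = tri[:, 0]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-14
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)

    tz = tri[:, :, 2]
    tz_min, tz_max = tz.min(axis=1), tz.max(axis=1)

    # worst-case drift of the ray's z coordinate over the mesh's x extent
    bmin, bmax = mesh.bounds
    x_span = max(bmax[0] - min(bmin[0], pts[:, 0].min()), 0.0)
    drift = abs(d[2] / d[0]) * x_span + 1e-9 if d[0] != 0 else np.inf

    inside = np.zeros(len(pts), dtype=bool)
    order = np.argsort(pts[:, 2], kind="stable")
    for start in range(0, len(order), chunk):
        idx = order[start : start + chunk]
        p = pts[idx]
        zlo, zhi = p[:, 2].min(), p[:, 2].max()
        sel = ok & (tz_max >= zlo - drift) & (tz_min <= zhi + drift)
        if not np.any(sel):
            continue
        tvec = p[:, None, :] - v0[None, sel, :]
        u = np.einsum("pmk,mk->pm", tvec, pvec[sel]) * inv_det[sel]
        qvec = np.cross(tvec, e1[sel])
        v = np.einsum("pmk,k->pm", qvec, d) * inv_det[sel]
        t = np.einsum("pmk,mk->pm", qvec, e2[sel]) * inv_det[sel]
        hit = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0) & (t > 1e-12)
        inside[idx] = hit.sum(axis=1) % 2 == 1
    return bool(inside[0]) if single else inside


@dataclass
class OccupancyGrid:
    """Axis-aligned isotropic voxel grid with a boolean occupancy array.

    Voxel ``(i, j, k)`` has its center at ``origin + (i+.5, j+.5, k+.5) * h``.
    """

    origin: np.ndarray
    spacing: float
    occupancy: np.ndarray  # bool, shape == dims

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D boolean array")

    @property
    def dims(self):
        return self.occupancy.shape

    @property
    def volume(self) -> float:
        """Occupied volume (mm^3) = occupied-voxel count x h^3."""
        return float(np.count_nonzero(self.occupancy)) * self.spacing**3

    def occupied_centers(self) -> np.ndarray:
        """(n, 3) array of occupied voxel centers."""
        ijk = np.argwhere(self.occupancy)
        return self.origin + (ijk + 0.5) * self.spacing

    def with_occupancy(self, occupancy: np.ndarray) -> "OccupancyGrid":
        """Same geometry, different occupancy (e.g. after a plane cut)."""
        occ = np.asarray(occupancy, dtype=bool)
        if occ.shape != self.occupancy.shape:
            raise ValueError("occupancy shape mismatch")
        return OccupancyGrid(self.origin.copy(), self.spacing, occ)

    def to_voxel_csv(self, path):
        """Dump occupied voxel indices as CSV rows ``i,j,k``."""
        ijk = np.argwhere(self.occupancy)
        np.savetxt(path, ijk, fmt="%d", delimiter=",", header="i,j,k", comments="")


def voxelize(mesh: TriangleMesh, h: float, bounds=None) -> OccupancyGrid:
    """Voxelize a watertight mesh at isotropic pitch ``h`` (mm).

    A voxel is occupied iff its center passes the ray-parity inside test.
    The grid covers the mesh bounds (or the given bounds) padded by at
    least one voxel on every side.
    """
    if h <= 0:
        raise ValueError("voxel pitch h must be positive")
    mesh.require_watertight("voxelization")
    if bounds is None:
        bmin, bmax = mesh.bounds
    else:
        bmin = np.asarray(bounds[0], dtype=float)
        bmax = np.asarray(bounds[1], dtype=float)
    origin = bmin - h
    dims = np.maximum(np.ceil((bmax + h - origin) / h).astype(int), 1)
    ii, jj, kk = np.meshgrid(
        np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]), indexing="ij"
    )
    centers = origin + (np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) + 0.5) * h
    occ = contains(mesh, centers).reshape(tuple(dims))
    return OccupancyGrid(origin, h, occ)


# -- primitive generators --------------------------------------------------

_BOX_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],  # z = lo
        [4, 5, 6], [4, 6, 7],  # z = hi
        [0, 1, 5], [0, 5, 4],  # y = lo
        [2, 3, 7], [2, 7, 6],  # y = hi
        [0, 4, 7], [0, 7, 3],  # x = lo
        [1, 2, 6], [1, 6, 5],  # x = hi
    ]
)


def box_mesh(center=(0.0, 0.0, 0.0), size=(1.0, 1.0, 1.0)) -> TriangleMesh:
    """Axis-aligned box as 12 outward-oriented triangles."""
    c = np.asarray(center, dtype=float)
    s = np.asarray(size, dtype=float) / 2.0
    corners = np.array(
        [
            [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
            [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
        ],
        dtype=float,
    )
    return TriangleMesh(c + corners * s, _BOX_FACES)


def icosphere(radius: float = 1.0, subdivisions: int = 3, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Subdivided icosahedron projected onto a sphere; outward-oriented."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts[0])
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(subdivisions):
        verts_list = list(verts)
        midpoint = {}

        def mid(i, j):
            key = (min(i, j), max(i, j))
            if key not in midpoint:
                m = verts_list[i] + verts_list[j]
                m = m / np.linalg.norm(m)
                midpoint[key] = len(verts_list)
                verts_list.append(m)
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces)
    return TriangleMesh(np.asarray(center, dtype=float) + radius * verts, faces)


def ellipsoid_mesh(
    center=(0.0, 0.0, 0.0),
    semiaxes=(1.0, 1.0, 1.0),
    subdivisions: int = 3,
    rotation: RigidTransform | None = None,
) -> TriangleMesh:
    """Ellipsoid from an anisotropically scaled icosphere.

    ``rotation`` (if given) is applied about ``center`` after scaling.
    """
    sph = icosphere(1.0, subdivisions)
    v = sph.vertices * np.asarray(semiaxes, dtype=float)
    if rotation is not None:
        v = v @ rotation.rotation.T
    return TriangleMesh(np.asarray(center, dtype=float) + v, sph.faces)
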