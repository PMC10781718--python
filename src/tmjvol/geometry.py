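"""Planes and rigid transforms.

Everything downstream — reference frames, voxel partitioning, serial-scan
superimposition — is phrased in terms of the two primitives here: an
oriented infinite :class:`Plane` (unit normal + a point on the plane) and a
proper :class:`RigidTransform` (rotation + translation, no scale, no
reflection).  Coordinates are millimetres in a right-handed frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GEOM_TOL

__all__ = [
    "DegenerateGeometryError",
    "Plane",
    "RigidTransform",
    "plane_from_three_points",
    "plane_perpendicular_through_line",
    "plane_perpendicular_to_two",
    "plane_parallel_through_point",
    "signed_distance",
    "transform_plane",
    "rotation_about_axis",
]


class DegenerateGeometryError(ValueError):
    """Raised when input points/planes do not determine the requested object."""


def as_point(p) -> np.ndarray:
    """Coerce to a finite float (3,) array."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"point has non-finite components: {arr}")
    return arr


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"cannot normalize near-zero {what}")
    return v / n


@dataclass(frozen=True)
class Plane:
    """Oriented infinite plane: unit ``normal`` and a ``point`` on the plane."""

    normal: np.ndarray
    point: np.ndarray

    def __post_init__(self):
        n = as_point(self.normal)
        n = _unit(n, "plane normal")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "point", as_point(self.point))

    def flipped(self) -> "Plane":
        """Same plane with the opposite orientation."""
        return Plane(-self.normal, self.point)

    def oriented_towards(self, p) -> "Plane":
        """Return this plane oriented so ``p`` lies on the positive side."""
        if signed_distance(self, p) < 0:
            return self.flipped()
        return self


def signed_distance(plane: Plane, p):
    """Signed distance (mm) of point(s) ``p`` from ``plane``.

    Positive on the side the normal points to.  Accepts a single (3,)
    point or an (n, 3) array.
    """
    arr = np.asarray(p, dtype=float)
    d = (arr - plane.point) @ plane.normal
    return float(d) if arr.ndim == 1 else d


def plane_from_three_points(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points.

    Normal is the normalized ``(p2 - p1) x (p3 - p1)``.
    """
    p1, p2, p3 = as_point(p1), as_point(p2), as_point(p3)
    cross = np.cross(p2 - p1, p3 - p1)
    if np.linalg.norm(cross) / 2.0 <= GEOM_TOL:  # triangle area in mm^2
        raise DegenerateGeometryError(
            "three points are collinear or coincident; they do not define a plane"
        )
    return Plane(cross, p1)


def plane_perpendicular_through_line(base: Plane, a, b) -> Plane:
    """Plane perpendicular to ``base`` containing the line through ``a`` and ``b``.

    Normal is ``normalize((b - a) x base.normal)``.
    """
    a, b = as_point(a), as_point(b)
    ab = b - a
    if np.linalg.norm(ab) < 1e-12:
        raise DegenerateGeometryError("the two through-points coincide")
    cross = np.cross(ab, base.normal)
    if np.linalg.norm(cross) <= GEOM_TOL * max(1.0, np.linalg.norm(ab)):
        raise DegenerateGeometryError(
            "line direction is parallel to the base normal; plane is undetermined"
        )
    return Plane(cross, a)


def plane_perpendicular_to_two(p1: Plane, p2: Plane, through) -> Plane:
    """Plane through ``through`` perpendicular to both input planes."""
    cross = np.cross(p1.normal, p2.normal)
    if np.linalg.norm(cross) <= GEOM_TOL:
        raise DegenerateGeometryError("input plane normals are parallel")
    return Plane(cross, as_point(through))


def plane_parallel_through_point(base: Plane, p) -> Plane:
    """Plane parallel to ``base`` (same normal) through ``p``."""
    return Plane(base.normal, as_point(p))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = as_point(self.translation)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation matrix must have determinant +1 (no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points):
        """Apply to a (3,) point or (n, 3) array of points."""
        arr = np.asarray(points, dtype=float)
        return arr @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Rotation angle of the transform, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def transform_plane(T: RigidTransform, plane: Plane) -> Plane:
    """Image of ``plane`` under the rigid motion ``T``."""
    return Plane(T.rotation @ plane.normal, T.apply(plane.point))


def rotation_about_axis(axis, angle_deg: float, center=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Rigid rotation by ``angle_deg`` about the line through ``center`` along ``axis``."""
    k = _unit(as_point(axis), "rotation axis")
    c = as_point(center)
    th = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    return RigidTransform(R, c - R @ c)
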