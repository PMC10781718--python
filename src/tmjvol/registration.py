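"""Serial-scan superimposition: landmark registration and ICP refinement.

The first alignment of a follow-up scan onto baseline is a least-squares
rigid fit (Kabsch) of three cranial landmarks that surgery does not move.
Remaining small discrepancies can then be rectified by point-to-point ICP
restricted to the cranial region.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    DegenerateGeometryError,
    Plane,
    RigidTransform,
    signed_distance,
)
from .mesh import TriangleMesh

__all__ = [
    "EmptyRegionError",
    "kabsch",
    "rigid_from_three_correspondences",
    "icp_refine",
]


class EmptyRegionError(ValueError):
    """Raised when the ICP region contains no moving vertices."""


def kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping ``src`` onto ``dst``.

    Minimizes sum |R s_i + t - d_i|^2 over rotations R (det +1) and
    translations t.  No scaling, no reflection.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3 or len(src) < 3:
        raise ValueError("src and dst must be matching (n>=3, 3) arrays")
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cd - R @ cs)


def _check_not_collinear(points: np.ndarray, label: str):
    area = np.linalg.norm(np.cross(points[1] - points[0], points[2] - points[0])) / 2.0
    if area <= 1e-9:
        raise DegenerateGeometryError(
            f"{label} landmark triple is collinear or coincident (area {area:.3g} mm^2)"
        )


def rigid_from_three_correspondences(src, dst) -> RigidTransform:
    """Three-landmark rigid superimposition (least-squares Kabsch fit).

    The two landmark triangles need not be congruent; the fit absorbs
    landmark placement noise without scaling or reflection.
    """
    src = np.asarray(src, dtype=float).reshape(3, 3)
    dst = np.asarray(dst, dtype=float).reshape(3, 3)
    _check_not_collinear(src, "source")
    _check_not_collinear(dst, "destination")
    return kabsch(src, dst)


def _rms(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def icp_refine(
    moving: TriangleMesh,
    fixed: TriangleMesh,
    init: RigidTransform,
    region: Plane,
    max_iter: int = 50,
    tol: float = 1e-6,
    rejection_factor: float = 2.0,
) -> RigidTransform:
    """Point-to-point ICP restricted to moving vertices in a half-space.

    Only moving vertices on the positive side of ``region`` (under ``init``)
    participate.  Correspondences farther than ``rejection_factor`` x the
    median nearest-neighbor distance are rejected each iteration.  The
    returned transform never has a larger restricted-region RMS than
    ``init``.
    """
    if len(moving.vertices) == 0 or len(fixed.vertices) == 0:
        raise ValueError("both meshes must be non-empty")
    pts0 = init.apply(moving.vertices)
    mask = signed_distance(region, pts0) > 0
    if not np.any(mask):
        raise EmptyRegionError("no moving vertices on the positive side of the region plane")
    sel = moving.vertices[mask]

    tree = cKDTree(fixed.vertices)

    def region_rms(T: RigidTransform) -> float:
        d, _ = tree.query(T.apply(sel))
        return float(np.sqrt(np.mean(d**2)))

    best = init
    best_rms = prev_rms = region_rms(init)
    T = init
    for _ in range(max_iter):
        p = T.apply(sel)
        dist, idx = tree.query(p)
        med = np.median(dist)
        keep = dist <= rejection_factor * max(med, 1e-12)
        if np.count_nonzero(keep) < 3:
            keep = np.ones(len(sel), dtype=bool)
        T = kabsch(sel[keep], fixed.vertices[idx[keep]])
        rms = region_rms(T)
        if rms < best_rms:
            best, best_rms = T, rms
        if abs(prev_rms - rms) < tol:
            break
        prev_rms = rms
    return best
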