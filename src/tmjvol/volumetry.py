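"""Joint-space volume extraction and compartmental partitioning.

The measurement chain per side and timepoint:

1. Voxelize the closed fossa region-of-interest mesh and keep the voxels
   superior to the side's eminence plane — that is the glenoid fossa
   volume ``Vgf``.
2. Remove voxels occupied by the (superimposed) mandible — the remainder
   is the joint space ``Vjs``.
3. Partition the joint-space voxels by the fossa coronal plane (GfCP) into
   anterior/posterior (``Vajs``/``Vpjs``) and by the fossa sagittal plane
   (GfSP) into medial/lateral (``Vmjs``/``Vljs``).

The fossa does not change after surgery, so follow-up timepoints reuse the
baseline fossa grid verbatim and only the mandible (rigidly mapped into
the baseline frame by the cranial superimposition) moves.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import DEFAULT_VOXEL_PITCH
from .frames import LandmarkSet, ReferenceFrame, build_reference_frame
from .geometry import RigidTransform, signed_distance
from .mesh import OccupancyGrid, TriangleMesh, contains, voxelize
from .registration import icp_refine, rigid_from_three_correspondences

__all__ = [
    "EmptyFossaError",
    "FossaROI",
    "JointSpaceVolumes",
    "TimepointCase",
    "compute_vgf",
    "compute_joint_space",
    "measure_timepoint",
    "measure_series",
    "superimpose_case",
    "percent_change",
    "volumes_to_frame",
]

TIMEPOINTS = ("T0", "T1", "T2", "T3")

#: landmarks used for the 3-point cranial superimposition
SUPERIMPOSITION_LANDMARKS = ("N", "PoR", "Ba")


class EmptyFossaError(ValueError):
    """No fossa voxels superior to the eminence plane."""


@dataclass
class FossaROI:
    """Closed mesh bounding the fossa capture region for one side."""

    mesh: TriangleMesh
    side: str

    def __post_init__(self):
        if self.side not in ("R", "L"):
            raise ValueError(f"side must be 'R' or 'L', got {self.side!r}")


@dataclass
class JointSpaceVolumes:
    """The six volume outcomes (mm^3) for one side at one timepoint."""

    Vgf: float
    Vjs: float
    Vajs: float
    Vpjs: float
    Vmjs: float
    Vljs: float
    side: str
    timepoint: str
    h: float
    patient_id: str = ""

    def __post_init__(self):
        for name in ("Vgf", "Vjs", "Vajs", "Vpjs", "Vmjs", "Vljs"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} is negative: {v}")
        if self.Vjs > self.Vgf + 1e-9:
            raise ValueError("Vjs exceeds Vgf")
        h3 = self.h**3
        if abs(self.Vajs + self.Vpjs - self.Vjs) > 1e-9 * max(1.0, self.Vjs / h3):
            raise ValueError("Vajs + Vpjs != Vjs")
        if abs(self.Vmjs + self.Vljs - self.Vjs) > 1e-9 * max(1.0, self.Vjs / h3):
            raise ValueError("Vmjs + Vljs != Vjs")

    def as_record(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "side": self.side,
            "timepoint": self.timepoint,
            "h_mm": self.h,
            **{k: round(getattr(self, k), 2) for k in ("Vgf", "Vjs", "Vajs", "Vpjs", "Vmjs", "Vljs")},
        }


@dataclass
class TimepointCase:
    """One scan: cranial + mandible meshes, landmarks, optional fossa ROIs."""

    patient_id: str
    timepoint: str
    mandible: TriangleMesh
    landmarks: LandmarkSet
    cranial: Optional[TriangleMesh] = None
    rois: dict = field(default_factory=dict)  # side -> FossaROI (baseline only)
    to_t0: Optional[RigidTransform] = None  # precomputed superimposition

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")


def compute_vgf(roi: FossaROI, frame: ReferenceFrame, h: float = DEFAULT_VOXEL_PITCH):
    """Glenoid fossa volume: ROI voxels strictly superior to the side's EmP.

    Returns ``(Vgf, fossa_grid)``; the grid (already cut at EmP) is reused
    for the joint-space measurements at every timepoint.
    """
    grid = voxelize(roi.mesh, h)
    emp = frame.EmP[roi.side]
    centers_all = grid.origin + (
        np.stack(
            np.meshgrid(
                np.arange(grid.dims[0]), np.arange(grid.dims[1]), np.arange(grid.dims[2]),
                indexing="ij",
            ),
            axis=-1,
        ).reshape(-1, 3)
        + 0.5
    ) * grid.spacing
    above = (signed_distance(emp, centers_all) > 0).reshape(grid.dims)
    kept = grid.occupancy & above
    if not np.any(kept):
        raise EmptyFossaError(
            f"fossa ROI ({roi.side}) has no voxels superior to EmP{roi.side}"
        )
    fossa_grid = grid.with_occupancy(kept)
    return fossa_grid.volume, fossa_grid


def compute_joint_space(
    fossa_grid: OccupancyGrid,
    mandible: TriangleMesh,
    frame: ReferenceFrame,
    side: str,
    timepoint: str = "T0",
    patient_id: str = "",
) -> JointSpaceVolumes:
    """All six volumes from a fossa grid and a (superimposed) mandible.

    Joint-space voxels are the fossa voxels whose centers are not inside
    the mandible.  Voxel centers exactly on GfCP go to the anterior bin;
    exactly on GfSP, to the medial bin (deterministic tie-breaking).
    """
    h = fossa_grid.spacing
    centers = fossa_grid.occupied_centers()
    vgf = fossa_grid.volume

    # bounding-box prefilter: a center outside the mandible box is outside
    in_mand = np.zeros(len(centers), dtype=bool)
    bmin, bmax = mandible.bounds
    near = np.all((centers >= bmin) & (centers <= bmax), axis=1)
    if np.any(near):
        in_mand[near] = contains(mandible, centers[near])
    js = centers[~in_mand]

    h3 = h**3
    vjs = len(js) * h3

    gfcp = frame.GfCP[side]
    gfsp = frame.GfSP[side]
    d_ap = signed_distance(gfcp, js) if len(js) else np.empty(0)
    d_ml = signed_distance(gfsp, js) if len(js) else np.empty(0)
    n_ant = int(np.count_nonzero(d_ap >= 0))  # ties -> anterior
    n_med = int(np.count_nonzero(d_ml <= 0))  # ties -> medial
    return JointSpaceVolumes(
        Vgf=vgf,
        Vjs=vjs,
        Vajs=n_ant * h3,
        Vpjs=(len(js) - n_ant) * h3,
        Vmjs=n_med * h3,
        Vljs=(len(js) - n_med) * h3,
        side=side,
        timepoint=timepoint,
        h=h,
        patient_id=patient_id,
    )


def superimpose_case(
    case: TimepointCase,
    t0: TimepointCase,
    refine: bool = False,
    frame_t0: Optional[ReferenceFrame] = None,
) -> RigidTransform:
    """Rigid transform mapping a follow-up scan into the baseline frame.

    Least-squares fit of the (N, PoR, Ba) cranial landmarks, optionally
    refined by ICP over the cranial region (positive side of the baseline
    mid-axial plane).
    """
    if case.to_t0 is not None:
        return case.to_t0
    src = np.array([case.landmarks[k] for k in SUPERIMPOSITION_LANDMARKS])
    dst = np.array([t0.landmarks[k] for k in SUPERIMPOSITION_LANDMARKS])
    T = rigid_from_three_correspondences(src, dst)
    if refine:
        if case.cranial is None or t0.cranial is None:
            raise ValueError("ICP refinement requires cranial meshes on both cases")
        if frame_t0 is None:
            frame_t0 = build_reference_frame(t0.landmarks)
        T = icp_refine(case.cranial, t0.cranial, T, region=frame_t0.MAP)
    return T


def measure_timepoint(
    t0: TimepointCase,
    case: TimepointCase,
    frame_t0: ReferenceFrame,
    side: str,
    h: float = DEFAULT_VOXEL_PITCH,
    refine: bool = False,
    fossa_grid: Optional[OccupancyGrid] = None,
) -> JointSpaceVolumes:
    """Measure one side of one timepoint against the baseline fossa.

    The baseline fossa grid is computed from ``t0``'s ROI (or passed in,
    to amortize voxelization across timepoints); the case's mandible is
    rigidly superimposed into the baseline frame via the cranial landmarks
    before condyle removal.  ``Vgf`` in the result is the baseline value
    by construction.
    """
    if fossa_grid is None:
        if side not in t0.rois:
            raise ValueError(f"baseline case has no fossa ROI for side {side!r}")
        _, fossa_grid = compute_vgf(t0.rois[side], frame_t0, h)
    T = superimpose_case(case, t0, refine=refine, frame_t0=frame_t0)
    mandible = case.mandible.transformed(T)
    return compute_joint_space(
        fossa_grid, mandible, frame_t0, side,
        timepoint=case.timepoint, patient_id=case.patient_id,
    )


def measure_series(
    cases: dict,
    side: str,
    h: float = DEFAULT_VOXEL_PITCH,
    refine: bool = False,
) -> dict:
    """Measure every timepoint of a serial-scan set against the T0 fossa.

    ``cases`` maps timepoint labels to :class:`TimepointCase`; the T0 case
    must carry the fossa ROI for ``side``.  The fossa grid is voxelized
    once and reused, so longitudinal differences reflect condyle position
    only.  Returns ``{timepoint: JointSpaceVolumes}``.
    """
    if "T0" not in cases:
        raise ValueError("a T0 baseline case is required")
    t0 = cases["T0"]
    frame_t0 = build_reference_frame(t0.landmarks)
    if side not in t0.rois:
        raise ValueError(f"baseline case has no fossa ROI for side {side!r}")
    _, fossa_grid = compute_vgf(t0.rois[side], frame_t0, h)
    return {
        tp: measure_timepoint(
            t0, case, frame_t0, side, h=h, refine=refine, fossa_grid=fossa_grid
        )
        for tp, case in cases.items()
    }


def percent_change(diff: float, baseline: float) -> float:
    """Percentage change ``100 * diff / baseline`` (baseline must be > 0)."""
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return 100.0 * diff / baseline


def volumes_to_frame(volumes) -> pd.DataFrame:
    """Tabulate measurements (columns per the output CSV contract)."""
    return pd.DataFrame(
        [v.as_record() for v in volumes],
        columns=["patient_id", "side", "timepoint", "h_mm", "Vgf", "Vjs", "Vajs", "Vpjs", "Vmjs", "Vljs"],
    )
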