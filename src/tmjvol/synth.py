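"""Synthetic phantoms and longitudinal record simulation.

Two generators make every pipeline stage testable without patient data:

* a geometric phantom — half-ellipsoid fossa capture region, ellipsoid
  condyle, analytically placed landmarks — with a condylar
  sagging-then-partial-recovery displacement across four visits and a
  random rigid "scanner pose" per visit so the superimposition chain is
  exercised end to end;
* a long-format volume record simulator with per-joint 4-visit
  correlation, a shared patient-level component between the two joints of
  a patient, and missingness of the day-3 visit.

Ellipsoids are used because closed-form volumes exist for the limiting
cases and their meshes are trivially watertight.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .frames import LandmarkSet
from .geometry import RigidTransform, rotation_about_axis
from .mesh import TriangleMesh, ellipsoid_mesh
from .reference_values import (
    ESTIMATED_MEANS,
    ESTIMATED_SES,
    N_JOINTS,
    N_PATIENTS,
    N_T1_OBSERVED,
    OUTCOMES,
    TIMEPOINTS,
)
from .volumetry import FossaROI, JointSpaceVolumes, TimepointCase

__all__ = [
    "PhantomSpecError",
    "PhantomSpec",
    "PhantomSeries",
    "SimSpec",
    "make_phantom_series",
    "oracle_volumes",
    "simulate_longitudinal_records",
    "default_sim_spec",
]


class PhantomSpecError(ValueError):
    """Phantom specification is geometrically inconsistent."""


# canonical landmark layout (mm): MAP is z=0, MSP is x=0, anterior is +y
_CANONICAL_LANDMARKS = {
    "N": (0.0, 55.0, 10.0),
    "OrR": (30.0, 40.0, 0.0),
    "OrL": (-30.0, 40.0, 0.0),
    "PoR": (40.0, -40.0, 0.0),
    "PoL": (-40.0, -40.0, 0.0),
    "Ba": (0.0, -45.0, -15.0),
    "Cg": (0.0, 45.0, 25.0),
}

#: fossa center of the right side; EmP passes through its z level
_FOSSA_CENTER_R = np.array([45.0, -35.0, 2.0])
_EM_R = np.array([50.0, -27.0, 2.0])


@dataclass
class PhantomSpec:
    """Parameters of the four-visit sagging phantom."""

    fossa_semiaxes: tuple = (10.0, 8.0, 6.0)
    condyle_semiaxes: tuple = (6.0, 5.0, 4.0)
    condyle_offset: tuple = (0.0, 0.0, -1.0)  # from fossa center, canonical frame
    sag_anterior: float = 1.5  # mm, T1 displacement components
    sag_medial: float = 1.0
    sag_inferior: float = 1.5
    sag_rotation_deg: float = 0.0  # about the osteotomy contact point
    rotation_center_offset: tuple = (0.0, -5.0, -15.0)  # from condyle center
    recovery_t2: float = 0.6  # fraction of the T1 displacement recovered
    recovery_t3: float = 0.6
    landmark_scale: float = 1.0
    landmark_jitter_mm: float = 0.0
    pose_rotation_deg: float = 5.0  # scanner-pose magnitude per visit
    pose_translation_mm: float = 8.0
    subdivisions: int = 4
    sides: tuple = ("R",)
    seed: int = 0

    def __post_init__(self):
        if min(self.fossa_semiaxes) <= 0 or min(self.condyle_semiaxes) <= 0:
            raise PhantomSpecError("all semi-axes must be positive")
        if not (0.0 <= self.recovery_t2 <= self.recovery_t3 <= 1.0):
            raise PhantomSpecError("recovery fractions must satisfy 0 <= rho2 <= rho3 <= 1")
        if any(s not in ("R", "L") for s in self.sides):
            raise PhantomSpecError(f"sides must be 'R'/'L', got {self.sides}")

    # -- canonical (unposed) geometry -------------------------------------

    def fossa_center(self, side: str) -> np.ndarray:
        sign = 1.0 if side == "R" else -1.0
        c = _FOSSA_CENTER_R * np.array([sign, 1.0, 1.0])
        return c * self.landmark_scale

    def condyle_center(self, side: str) -> np.ndarray:
        sign = 1.0 if side == "R" else -1.0
        off = np.asarray(self.condyle_offset, dtype=float) * np.array([sign, 1.0, 1.0])
        return self.fossa_center(side) + off

    def canonical_landmarks(self) -> dict:
        lm = {k: np.asarray(v) * self.landmark_scale for k, v in _CANONICAL_LANDMARKS.items()}
        c = self.fossa_semiaxes[2]
        for side, sign in (("R", 1.0), ("L", -1.0)):
            lm[f"Em{side}"] = _EM_R * np.array([sign, 1.0, 1.0]) * self.landmark_scale
            lm[f"Gf{side}"] = self.fossa_center(side) + np.array([0.0, 0.0, c])
        return lm

    def displacement(self, side: str, timepoint: str) -> RigidTransform:
        """Ground-truth condyle displacement at a visit, canonical frame.

        T1 applies the full sag (translation plus rotation about the
        osteotomy contact point); T2/T3 apply the fraction remaining
        after recovery; T0 is the identity.
        """
        if timepoint == "T0":
            return RigidTransform.identity()
        remaining = {"T1": 1.0, "T2": 1.0 - self.recovery_t2, "T3": 1.0 - self.recovery_t3}[
            timepoint
        ]
        sign = 1.0 if side == "R" else -1.0
        # canonical directions: anterior +y, superior +z, lateral_R +x
        translation = remaining * np.array(
            [-sign * self.sag_medial, self.sag_anterior, -self.sag_inferior]
        )
        T = RigidTransform(np.eye(3), translation)
        if self.sag_rotation_deg:
            center = self.condyle_center(side) + np.asarray(self.rotation_center_offset) * np.array(
                [sign, 1.0, 1.0]
            )
            rot = rotation_about_axis(
                (0.0, 0.0, 1.0), sign * remaining * self.sag_rotation_deg, center
            )
            T = T.compose(rot)
        return T


@dataclass
class PhantomSeries:
    """Four generated visits plus their ground-truth transforms."""

    spec: PhantomSpec
    cases: dict  # timepoint -> TimepointCase
    scanner_pose: dict  # timepoint -> RigidTransform (canonical -> scan coords)
    cranial_to_t0: dict  # timepoint -> RigidTransform (scan -> T0 scan coords)
    condyle_displacement: dict  # side -> timepoint -> RigidTransform (canonical)


def _random_pose(rng: np.random.Generator, max_deg: float, max_mm: float) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_deg, max_deg)
    t = rng.uniform(-max_mm, max_mm, size=3)
    R = rotation_about_axis(axis, angle).rotation
    return RigidTransform(R, t)


def _merge(meshes) -> TriangleMesh:
    verts, faces, offset = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        offset += len(m.vertices)
    return TriangleMesh(np.vstack(verts), np.vstack(faces))


def make_phantom_series(spec: PhantomSpec) -> PhantomSeries:
    """Generate the four visits of the sagging phantom.

    Each visit carries a cranial shell, the mandible (one ellipsoid condyle
    per requested side, displaced by that visit's sag state), jittered or
    exact landmarks, and — at baseline only — the closed fossa ROI
    mesh(es).  All geometry of a visit is moved by a seeded random scanner
    pose, so the measurement chain must superimpose before measuring.
    """
    rng = np.random.default_rng(spec.seed)

    # geometric consistency: the condyle must reach into the capture region
    for side in spec.sides:
        fc = spec.fossa_center(side)
        cc = spec.condyle_center(side)
        top = cc + np.array([0.0, 0.0, spec.condyle_semiaxes[2]])
        in_fossa = np.sum(((top - fc) / np.asarray(spec.fossa_semiaxes)) ** 2) <= 1.0
        if not (in_fossa and top[2] > fc[2]):
            raise PhantomSpecError(
                f"condyle ({side}) does not intersect the fossa capture region above EmP"
            )

    landmarks0 = spec.canonical_landmarks()
    cranial0 = ellipsoid_mesh(
        center=(0.0, 0.0, 5.0),
        semiaxes=np.array([55.0, 62.0, 45.0]) * spec.landmark_scale,
        subdivisions=spec.subdivisions,
    )
    condyles0 = {
        side: ellipsoid_mesh(spec.condyle_center(side), spec.condyle_semiaxes, spec.subdivisions)
        for side in spec.sides
    }

    cases, poses, cranial_to_t0 = {}, {}, {}
    displacement = {side: {} for side in spec.sides}
    for tp in TIMEPOINTS:
        pose = _random_pose(rng, spec.pose_rotation_deg, spec.pose_translation_mm)
        poses[tp] = pose
        lm = {}
        for name, p in landmarks0.items():
            jit = (
                rng.normal(scale=spec.landmark_jitter_mm, size=3)
                if spec.landmark_jitter_mm > 0
                else 0.0
            )
            lm[name] = pose.apply(np.asarray(p, dtype=float) + jit)
        parts = []
        for side in spec.sides:
            D = spec.displacement(side, tp)
            displacement[side][tp] = D
            parts.append(condyles0[side].transformed(pose.compose(D)))
        mandible = _merge(parts)
        rois = {}
        if tp == "T0":
            for side in spec.sides:
                roi_mesh = ellipsoid_mesh(
                    spec.fossa_center(side), spec.fossa_semiaxes, spec.subdivisions
                ).transformed(pose)
                rois[side] = FossaROI(roi_mesh, side)
        cases[tp] = TimepointCase(
            patient_id="phantom",
            timepoint=tp,
            mandible=mandible,
            landmarks=LandmarkSet(lm),
            cranial=cranial0.transformed(pose),
            rois=rois,
        )
    for tp in TIMEPOINTS:
        cranial_to_t0[tp] = poses["T0"].compose(poses[tp].inverse())
    return PhantomSeries(spec, cases, poses, cranial_to_t0, displacement)


def oracle_volumes(
    spec: PhantomSpec, timepoint: str, h_fine: float = 0.1, side: Optional[str] = None
) -> JointSpaceVolumes:
    """Independent brute-force volumes from the phantom's implicit geometry.

    Evaluates the analytic ellipsoid/half-space membership functions on its
    own fine grid in the canonical (unposed) frame — no meshes, no ray
    casting, a different grid origin convention, and z-slab accumulation
    instead of a stored occupancy array.  Serves as the oracle the voxel
    pipeline is checked against.
    """
    if side is None:
        side = spec.sides[0]
    if h_fine <= 0:
        raise ValueError("h_fine must be positive")
    fa = np.asarray(spec.fossa_semiaxes, dtype=float)
    ca = np.asarray(spec.condyle_semiaxes, dtype=float)
    fc = spec.fossa_center(side)
    z_em = fc[2]
    gf_x, gf_y = fc[0], fc[1]
    lateral_sign = 1.0 if side == "R" else -1.0
    Dinv = spec.displacement(side, timepoint).inverse()
    cc = spec.condyle_center(side)

    lo, hi = fc - fa, fc + fa
    nx, ny, nz = (np.ceil((hi - lo) / h_fine)).astype(int)
    xs = lo[0] + (np.arange(nx) + 0.5) * h_fine
    ys = lo[1] + (np.arange(ny) + 0.5) * h_fine
    zs = lo[2] + (np.arange(nz) + 0.5) * h_fine
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    n_gf = n_js = n_ant = n_med = 0
    for z in zs:
        if z <= z_em:
            continue  # Vgf keeps strictly-superior centers only
        in_fossa = ((X - fc[0]) / fa[0]) ** 2 + ((Y - fc[1]) / fa[1]) ** 2 + (
            (z - fc[2]) / fa[2]
        ) ** 2 <= 1.0
        if not np.any(in_fossa):
            continue
        pts = np.column_stack([X[in_fossa], Y[in_fossa], np.full(np.count_nonzero(in_fossa), z)])
        q = Dinv.apply(pts)
        in_cond = np.sum(((q - cc) / ca) ** 2, axis=1) <= 1.0
        js = pts[~in_cond]
        n_gf += len(pts)
        n_js += len(js)
        n_ant += int(np.count_nonzero(js[:, 1] - gf_y >= 0))  # anterior = +y; ties anterior
        n_med += int(np.count_nonzero(lateral_sign * (js[:, 0] - gf_x) <= 0))  # ties medial
    h3 = h_fine**3
    return JointSpaceVolumes(
        Vgf=n_gf * h3,
        Vjs=n_js * h3,
        Vajs=n_ant * h3,
        Vpjs=(n_js - n_ant) * h3,
        Vmjs=n_med * h3,
        Vljs=(n_js - n_med) * h3,
        side=side,
        timepoint=timepoint,
        h=h_fine,
        patient_id="oracle",
    )


# -- longitudinal record simulation ----------------------------------------


def default_covariance(outcome: str, correlation: float = 0.5) -> np.ndarray:
    """Default 4x4 visit covariance for an outcome.

    Visit SDs are back-computed from the published SEs of the estimated
    means as SD = SE * sqrt(70) (an approximation: the published SEs are
    model-based); visits share a common correlation.
    """
    sd = np.array([ESTIMATED_SES[outcome][tp] for tp in TIMEPOINTS]) * np.sqrt(N_JOINTS)
    R = np.full((4, 4), correlation)
    np.fill_diagonal(R, 1.0)
    return np.outer(sd, sd) * R


@dataclass
class SimSpec:
    """Parameters of the longitudinal record simulator."""

    means: dict = field(default_factory=lambda: {
        o: np.array([ESTIMATED_MEANS[o][tp] for tp in TIMEPOINTS]) for o in OUTCOMES
    })
    covariances: dict = field(default_factory=lambda: {
        o: default_covariance(o) for o in OUTCOMES
    })
    n_patients: int = N_PATIENTS
    joints_per_patient: int = 2
    n_t1_observed: int = N_T1_OBSERVED
    between_side_correlation: float = 0.5
    missingness: str = "mcar"  # or "high_t0": drop T1 for high-baseline patients
    seed: int = 0

    def __post_init__(self):
        for o, cov in self.covariances.items():
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (4, 4) or not np.allclose(cov, cov.T, atol=1e-8):
                raise ValueError(f"{o}: covariance must be symmetric 4x4")
            if np.min(np.linalg.eigvalsh((cov + cov.T) / 2)) < -1e-8:
                raise ValueError(f"{o}: covariance is not positive semi-definite")
            self.covariances[o] = cov
        if not (0 <= self.n_t1_observed <= self.n_patients):
            raise ValueError("n_t1_observed must be between 0 and n_patients")
        if not (0.0 <= self.between_side_correlation <= 1.0):
            raise ValueError("between_side_correlation must be in [0, 1]")
        if self.missingness not in ("mcar", "high_t0"):
            raise ValueError(f"unknown missingness mechanism {self.missingness!r}")


def default_sim_spec(seed: int = 0, **kwargs) -> SimSpec:
    return SimSpec(seed=seed, **kwargs)


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh((cov + cov.T) / 2)
    return V @ np.diag(np.sqrt(np.maximum(w, 0.0)))


def simulate_longitudinal_records(spec: SimSpec) -> pd.DataFrame:
    """Draw long-format volume records with the study's structure.

    Per outcome, each joint's 4-visit vector is mean + patient-level shared
    component (covariance rho*Sigma, common to the patient's joints) +
    joint-level residual ((1-rho)*Sigma), so each joint is marginally
    N(mean, Sigma) with between-side correlation rho per visit.  T1 rows
    are then deleted for the unobserved patients.  Fully seeded.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.between_side_correlation
    n_pat, jpp = spec.n_patients, spec.joints_per_patient
    sides = [f"J{j}" if jpp != 2 else ("R", "L")[j] for j in range(jpp)]

    rows = []
    t1_values_by_patient = {}
    for outcome in spec.means:
        mu = np.asarray(spec.means[outcome], dtype=float)
        cov = spec.covariances[outcome]
        A_pat = _psd_sqrt(rho * cov)
        A_jnt = _psd_sqrt((1.0 - rho) * cov)
        for p in range(n_pat):
            pid = f"P{p + 1:03d}"
            shared = A_pat @ rng.standard_normal(4)
            for side in sides:
                y = mu + shared + A_jnt @ rng.standard_normal(4)
                for tp, val in zip(TIMEPOINTS, y):
                    rows.append((pid, f"{pid}-{side}", tp, outcome, float(val)))
                if outcome == next(iter(spec.means)):
                    t1_values_by_patient.setdefault(pid, []).append(y[0])

    df = pd.DataFrame(rows, columns=["patient_id", "joint_id", "timepoint", "outcome", "value_mm3"])

    n_missing = n_pat - spec.n_t1_observed
    if n_missing > 0:
        patients = [f"P{p + 1:03d}" for p in range(n_pat)]
        if spec.missingness == "mcar":
            unobserved = rng.choice(patients, size=n_missing, replace=False)
        else:  # high_t0: patients with the highest baseline mean lose T1
            baseline = {pid: float(np.mean(v)) for pid, v in t1_values_by_patient.items()}
            unobserved = sorted(patients, key=lambda pid: -baseline[pid])[:n_missing]
        drop = df["timepoint"].eq("T1") & df["patient_id"].isin(list(unobserved))
        df = df[~drop].reset_index(drop=True)
    return df
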