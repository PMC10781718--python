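"""Anatomical landmarks, reference planes, and direction conventions.

Eleven named cranial landmarks define eight reference planes:

* MAP  — mid-axial plane through OrR, OrL and PoR
* MSP  — mid-sagittal plane, perpendicular to MAP through Cg and Ba
* COP  — coronal plane, perpendicular to MAP and MSP through Ba
* EmP  — per side, parallel to MAP through the eminence point Em
* GfSP — per side, parallel to MSP through the fossa point Gf
* GfCP — per side, parallel to COP through the fossa point Gf

Direction conventions (not anatomically canonical, but unambiguous in any
valid skull and recorded in output metadata): superior is the MAP normal
oriented toward Cg, anterior is the COP normal oriented toward N, and
lateral per side is the MSP normal oriented from MSP toward that side's Gf.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    Plane,
    as_point,
    plane_from_three_points,
    plane_parallel_through_point,
    plane_perpendicular_through_line,
    plane_perpendicular_to_two,
    signed_distance,
)

__all__ = [
    "LANDMARK_NAMES",
    "SIDES",
    "LandmarkSet",
    "ReferenceFrame",
    "CephLandmarks2D",
    "build_reference_frame",
    "diagnose_prognathism",
    "read_landmarks",
    "write_landmarks",
]

LANDMARK_NAMES = ("N", "OrR", "OrL", "PoR", "PoL", "Ba", "Cg", "EmR", "EmL", "GfR", "GfL")
SIDES = ("R", "L")

_PAIRED = (("OrR", "OrL"), ("PoR", "PoL"), ("EmR", "EmL"), ("GfR", "GfL"))

#: threshold (mm) for diagnosing prognathism: pogonion strictly more than
#: 1 mm anterior to the nasion perpendicular
PROGNATHISM_THRESHOLD_MM = 1.0


@dataclass(frozen=True)
class LandmarkSet:
    """The eleven named cranial reference points (mm)."""

    points: dict

    def __post_init__(self):
        pts = {name: as_point(p) for name, p in self.points.items()}
        missing = set(LANDMARK_NAMES) - set(pts)
        extra = set(pts) - set(LANDMARK_NAMES)
        if missing:
            raise ValueError(f"missing landmarks: {sorted(missing)}")
        if extra:
            raise ValueError(f"unknown landmarks: {sorted(extra)}")
        for a, b in _PAIRED:
            if np.allclose(pts[a], pts[b]):
                raise DegenerateGeometryError(f"paired landmarks {a}/{b} coincide")
        object.__setattr__(self, "points", pts)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def transformed(self, T) -> "LandmarkSet":
        return LandmarkSet({name: T.apply(p) for name, p in self.points.items()})

    def as_dict(self) -> dict:
        return {name: list(map(float, p)) for name, p in self.points.items()}


@dataclass(frozen=True)
class ReferenceFrame:
    """The eight reference planes plus oriented direction vectors."""

    MAP: Plane
    MSP: Plane
    COP: Plane
    EmP: dict  # side -> Plane
    GfSP: dict  # side -> Plane
    GfCP: dict  # side -> Plane
    superior: np.ndarray
    anterior: np.ndarray
    lateral: dict  # side -> unit vector

    def as_dict(self) -> dict:
        def plane_dict(p: Plane) -> dict:
            return {"normal": list(map(float, p.normal)), "point": list(map(float, p.point))}

        return {
            "planes": {
                "MAP": plane_dict(self.MAP),
                "MSP": plane_dict(self.MSP),
                "COP": plane_dict(self.COP),
                **{f"EmP{s}": plane_dict(self.EmP[s]) for s in SIDES},
                **{f"GfSP{s}": plane_dict(self.GfSP[s]) for s in SIDES},
                **{f"GfCP{s}": plane_dict(self.GfCP[s]) for s in SIDES},
            },
            "directions": {
                "superior": list(map(float, self.superior)),
                "anterior": list(map(float, self.anterior)),
                **{f"lateral_{s}": list(map(float, self.lateral[s])) for s in SIDES},
            },
            "conventions": {
                "superior": "MAP normal oriented toward Cg",
                "anterior": "COP normal oriented toward N",
                "lateral": "MSP normal oriented from MSP toward the side's Gf",
            },
        }


def _named(fn, names, *args):
    try:
        return fn(*args)
    except DegenerateGeometryError as exc:
        raise DegenerateGeometryError(f"{'/'.join(names)}: {exc}") from exc


def build_reference_frame(landmarks: LandmarkSet) -> ReferenceFrame:
    """Construct all reference planes and direction vectors from landmarks."""
    lm = landmarks
    MAP = _named(
        plane_from_three_points, ("OrR", "OrL", "PoR"), lm["OrR"], lm["OrL"], lm["PoR"]
    ).oriented_towards(lm["Cg"])
    MSP = _named(plane_perpendicular_through_line, ("Cg", "Ba"), MAP, lm["Cg"], lm["Ba"])
    COP = _named(
        plane_perpendicular_to_two, ("MAP", "MSP", "Ba"), MAP, MSP, lm["Ba"]
    ).oriented_towards(lm["N"])

    superior = MAP.normal
    anterior = COP.normal

    EmP, GfSP, GfCP, lateral = {}, {}, {}, {}
    for s in SIDES:
        EmP[s] = plane_parallel_through_point(MAP, lm[f"Em{s}"])
        gf = lm[f"Gf{s}"]
        gf_side = plane_parallel_through_point(MSP, gf)
        if signed_distance(MSP, gf) < 0:
            gf_side = gf_side.flipped()
        GfSP[s] = gf_side
        lateral[s] = gf_side.normal
        GfCP[s] = plane_parallel_through_point(COP, gf)
        # sanity: the articular eminence must sit anterior to the fossa
        if signed_distance(GfCP[s], lm[f"Em{s}"]) <= 0:
            raise DegenerateGeometryError(
                f"Em{s} is not anterior to GfCP{s}; landmark layout is inconsistent"
            )

    # right- and left-side landmarks must fall on opposite sides of MSP
    for a, b in _PAIRED:
        da, db = signed_distance(MSP, lm[a]), signed_distance(MSP, lm[b])
        if da * db >= 0:
            raise DegenerateGeometryError(
                f"{a}/{b}: paired landmarks are on the same side of the mid-sagittal plane"
            )

    return ReferenceFrame(MAP, MSP, COP, EmP, GfSP, GfCP, superior, anterior, lateral)


# -- 2D cephalometric prognathism rule -------------------------------------


@dataclass(frozen=True)
class CephLandmarks2D:
    """Lateral cephalogram landmarks (mm, 2D image plane)."""

    porion: np.ndarray
    orbitale: np.ndarray
    nasion: np.ndarray
    pogonion: np.ndarray

    def __post_init__(self):
        for name in ("porion", "orbitale", "nasion", "pogonion"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (2,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 2-vector")
            object.__setattr__(self, name, v)


def diagnose_prognathism(ceph: CephLandmarks2D):
    """Classify mandibular prognathism from a lateral cephalogram.

    The Frankfort horizontal (FH) runs through porion and orbitale; the
    vertical reference is the perpendicular to FH through nasion.  Returns
    ``(label, distance_mm)`` where the signed distance is the pogonion's
    anterior offset from the vertical reference (anterior = the
    porion-to-orbitale direction along FH) and the label is
    ``"prognathism"`` iff the offset strictly exceeds 1 mm.
    """
    fh = ceph.orbitale - ceph.porion
    norm = np.linalg.norm(fh)
    if norm < 1e-12:
        raise DegenerateGeometryError("porion and orbitale coincide; FH line undefined")
    forward = fh / norm
    distance = float(forward @ (ceph.pogonion - ceph.nasion))
    label = "prognathism" if distance > PROGNATHISM_THRESHOLD_MM else "not prognathism"
    return label, distance


# -- landmark file I/O -----------------------------------------------------


def read_landmarks(path, strict: bool = True) -> LandmarkSet:
    """Read a ``{"name": [x, y, z], ...}`` JSON landmark file.

    Strict mode (default) rejects unknown keys; non-strict drops them.
    """
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: landmark file must be a JSON object")
    if not strict:
        data = {k: v for k, v in data.items() if k in LANDMARK_NAMES}
    return LandmarkSet({k: np.asarray(v, dtype=float) for k, v in data.items()})


def write_landmarks(landmarks: LandmarkSet, path):
    Path(path).write_text(json.dumps(landmarks.as_dict(), indent=2) + "\n")
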