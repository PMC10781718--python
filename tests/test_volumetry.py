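import numpy as np
import pandas as pd
import pytest

from tmjvol.frames import LandmarkSet, build_reference_frame
from tmjvol.mesh import box_mesh, ellipsoid_mesh, icosphere
from tmjvol.synth import PhantomSpec, make_phantom_series
from tmjvol.volumetry import (
    EmptyFossaError,
    FossaROI,
    JointSpaceVolumes,
    TimepointCase,
    compute_joint_space,
    compute_vgf,
    measure_series,
    measure_timepoint,
    percent_change,
    volumes_to_frame,
)

FOSSA_CENTER = np.array([45.0, -35.0, 2.0])  # EmP passes through z=2
HALF_ELLIPSOID = 2.0 / 3.0 * np.pi * 10 * 8 * 6  # 1005.31 mm^3
SPHERE4 = 4.0 / 3.0 * np.pi * 4.0**3  # 268.08 mm^3

FAR_MANDIBLE = box_mesh(center=(200, 200, 200), size=(5, 5, 5))


@pytest.fixture(scope="module")
def fossa_roi():
    return FossaROI(ellipsoid_mesh(FOSSA_CENTER, (10, 8, 6), subdivisions=4), "R")


@pytest.fixture(scope="module")
def fine_grid(fossa_roi, canonical_frame):
    vgf, grid = compute_vgf(fossa_roi, canonical_frame, h=0.25)
    return vgf, grid


@pytest.fixture(scope="module")
def mid_grid(fossa_roi, canonical_frame):
    return compute_vgf(fossa_roi, canonical_frame, h=0.3)


class TestComputeVgf:
    def test_half_ellipsoid_closed_form(self, fine_grid):
        vgf, _ = fine_grid
        assert vgf == pytest.approx(HALF_ELLIPSOID, rel=1e-2)

    def test_roi_below_emp_raises(self, canonical_frame):
        low = FossaROI(
            ellipsoid_mesh(FOSSA_CENTER - [0, 0, 12], (10, 8, 6), subdivisions=2), "R"
        )
        with pytest.raises(EmptyFossaError):
            compute_vgf(low, canonical_frame, h=0.5)

    def test_refinement_study(self, fossa_roi, canonical_frame, fine_grid):
        coarse, _ = compute_vgf(fossa_roi, canonical_frame, h=0.5)
        fine, _ = fine_grid
        assert abs(coarse - fine) / fine < 1e-2


class TestComputeJointSpace:
    def test_empty_condyle_vjs_equals_vgf(self, mid_grid, canonical_frame):
        vgf, grid = mid_grid
        v = compute_joint_space(grid, FAR_MANDIBLE, canonical_frame, "R")
        assert v.Vjs == v.Vgf == pytest.approx(vgf)
        assert v.Vajs + v.Vpjs == pytest.approx(v.Vjs, abs=1e-12)
        assert v.Vmjs + v.Vljs == pytest.approx(v.Vjs, abs=1e-12)

    def test_symmetric_fossa_splits_evenly(self, fine_grid, canonical_frame):
        # the split planes pass through the centroid of a symmetric fossa,
        # so the anterior/posterior and medial/lateral halves must balance
        _, grid = fine_grid
        v = compute_joint_space(grid, FAR_MANDIBLE, canonical_frame, "R")
        assert abs(v.Vajs - v.Vpjs) / v.Vjs < 1e-2
        assert abs(v.Vmjs - v.Vljs) / v.Vjs < 1e-2

    def test_sphere_condyle_closed_form(self, canonical_landmarks, rng):
        # larger fossa so a radius-4 sphere fits entirely above EmP
        pts = dict(canonical_landmarks.points)
        pts["GfR"] = FOSSA_CENTER + [0, 0, 10]
        pts["GfL"] = FOSSA_CENTER * [-1, 1, 1] + [0, 0, 10]
        frame = build_reference_frame(LandmarkSet(pts))
        roi = FossaROI(ellipsoid_mesh(FOSSA_CENTER, (14, 12, 10), subdivisions=4), "R")
        vgf, grid = compute_vgf(roi, frame, h=0.25)
        sphere = icosphere(4.0, 4, center=FOSSA_CENTER + [0, 0, 5])
        v = compute_joint_space(grid, sphere, frame, "R")
        assert v.Vjs == pytest.approx(vgf - SPHERE4, rel=1.5e-2)

    def test_additivity_exact_at_every_resolution(
        self, fossa_roi, canonical_frame, default_measurements
    ):
        for h in (0.6, 0.4):
            _, grid = compute_vgf(fossa_roi, canonical_frame, h=h)
            condyle = ellipsoid_mesh(FOSSA_CENTER + [1, 1, -1], (6, 5, 4), subdivisions=2)
            v = compute_joint_space(grid, condyle, canonical_frame, "R")
            assert v.Vajs + v.Vpjs == pytest.approx(v.Vjs, abs=1e-9)
            assert v.Vmjs + v.Vljs == pytest.approx(v.Vjs, abs=1e-9)
        for v in default_measurements.values():
            assert v.Vajs + v.Vpjs == pytest.approx(v.Vjs, abs=1e-9)
            assert v.Vmjs + v.Vljs == pytest.approx(v.Vjs, abs=1e-9)

    def test_nestedness(self, mid_grid, canonical_frame, default_measurements):
        _, grid = mid_grid
        small = ellipsoid_mesh(FOSSA_CENTER, (3, 3, 3), subdivisions=2)
        big = ellipsoid_mesh(FOSSA_CENTER, (6, 5, 4), subdivisions=2)
        v_small = compute_joint_space(grid, small, canonical_frame, "R")
        v_big = compute_joint_space(grid, big, canonical_frame, "R")
        assert v_big.Vjs < v_small.Vjs <= v_small.Vgf
        for v in default_measurements.values():
            assert v.Vjs <= v.Vgf


class TestMeasureTimepoint:
    def make_case(self, timepoint, mandible, landmarks, roi=None):
        return TimepointCase(
            patient_id="p1",
            timepoint=timepoint,
            mandible=mandible,
            landmarks=landmarks,
            rois={"R": roi} if roi else {},
        )

    def test_identity_copy_reproduces_t0(self, canonical_landmarks, canonical_frame):
        roi = FossaROI(ellipsoid_mesh(FOSSA_CENTER, (10, 8, 6), subdivisions=3), "R")
        condyle = ellipsoid_mesh(FOSSA_CENTER + [0, 0, -1], (6, 5, 4), subdivisions=3)
        t0 = self.make_case("T0", condyle, canonical_landmarks, roi)
        copy = self.make_case("T2", condyle, canonical_landmarks)
        vgf, grid = compute_vgf(roi, canonical_frame, h=0.4)
        direct = compute_joint_space(grid, condyle, canonical_frame, "R")
        via = measure_timepoint(t0, copy, canonical_frame, "R", h=0.4)
        for k in ("Vgf", "Vjs", "Vajs", "Vpjs", "Vmjs", "Vljs"):
            assert getattr(via, k) == getattr(direct, k)
        assert via.timepoint == "T2"

    def test_whole_head_motion_equivariance(self):
        # zero sag, full recovery: only the scanner pose differs between
        # visits, so every visit must reproduce the T0 volumes within one
        # voxel layer of the fossa surface
        spec = PhantomSpec(
            seed=7, sag_anterior=0, sag_medial=0, sag_inferior=0,
            recovery_t2=1.0, recovery_t3=1.0, subdivisions=3,
        )
        series = make_phantom_series(spec)
        res = measure_series(series.cases, "R", h=0.4)
        layer = series.cases["T0"].rois["R"].mesh.area * 0.4
        for tp in ("T1", "T2", "T3"):
            for k in ("Vgf", "Vjs", "Vajs", "Vpjs", "Vmjs", "Vljs"):
                assert abs(getattr(res[tp], k) - getattr(res["T0"], k)) < layer

    def test_inferior_sag_monotone(self, mid_grid, canonical_frame):
        _, grid = mid_grid
        vols = []
        for dz in (0.0, 0.5, 1.0, 2.0):
            condyle = ellipsoid_mesh(
                FOSSA_CENTER + [0, 0, -1 - dz], (6, 5, 4), subdivisions=3
            )
            vols.append(compute_joint_space(grid, condyle, canonical_frame, "R").Vjs)
        assert all(b >= a for a, b in zip(vols, vols[1:]))
        assert vols[-1] > vols[0]

    def test_anterior_shift_moves_compartments(self, mid_grid, canonical_frame):
        _, grid = mid_grid
        base = compute_joint_space(
            grid,
            ellipsoid_mesh(FOSSA_CENTER + [0, 0, -1], (6, 5, 4), subdivisions=3),
            canonical_frame, "R",
        )
        shifted = compute_joint_space(
            grid,
            ellipsoid_mesh(FOSSA_CENTER + [0, 1.0, -1], (6, 5, 4), subdivisions=3),
            canonical_frame, "R",
        )
        assert shifted.Vpjs > base.Vpjs
        assert shifted.Vajs < base.Vajs

    def test_missing_roi_raises(self, canonical_landmarks, canonical_frame):
        condyle = ellipsoid_mesh(FOSSA_CENTER, (3, 3, 3), subdivisions=2)
        t0 = self.make_case("T0", condyle, canonical_landmarks)
        with pytest.raises(ValueError, match="no fossa ROI"):
            measure_timepoint(t0, t0, canonical_frame, "R", h=0.5)


class TestPercentChange:
    @pytest.mark.parametrize(
        "diff,baseline,expected",
        [(134.54, 1110.99, 12.11), (283.12, 544.10, 52.03), (0.0, 500.0, 0.00)],
    )
    def test_published_examples(self, diff, baseline, expected):
        assert round(percent_change(diff, baseline), 2) == expected

    @pytest.mark.parametrize("baseline", [0.0, -5.0])
    def test_nonpositive_baseline(self, baseline):
        with pytest.raises(ValueError):
            percent_change(10.0, baseline)


class TestOutputs:
    def test_volumes_to_frame_layout(self):
        v = JointSpaceVolumes(
            Vgf=1000.0, Vjs=800.123456, Vajs=400.061728, Vpjs=400.061728,
            Vmjs=500.0, Vljs=300.123456, side="R", timepoint="T1", h=0.3,
            patient_id="p9",
        )
        df = volumes_to_frame([v])
        assert list(df.columns) == [
            "patient_id", "side", "timepoint", "h_mm",
            "Vgf", "Vjs", "Vajs", "Vpjs", "Vmjs", "Vljs",
        ]
        assert df.loc[0, "Vjs"] == 800.12

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError, match="exceeds Vgf"):
            JointSpaceVolumes(
                Vgf=100.0, Vjs=200.0, Vajs=100.0, Vpjs=100.0, Vmjs=100.0,
                Vljs=100.0, side="R", timepoint="T0", h=0.3,
            )
        with pytest.raises(ValueError, match="negative"):
            JointSpaceVolumes(
                Vgf=100.0, Vjs=-1.0, Vajs=0.0, Vpjs=-1.0, Vmjs=0.0, Vljs=-1.0,
                side="R", timepoint="T0", h=0.3,
            )
        with pytest.raises(ValueError, match="Vajs"):
            JointSpaceVolumes(
                Vgf=100.0, Vjs=50.0, Vajs=10.0, Vpjs=10.0, Vmjs=25.0, Vljs=25.0,
                side="R", timepoint="T0", h=0.3,
            )

    def test_bad_timepoint_case(self, canonical_landmarks):
        with pytest.raises(ValueError, match="timepoint"):
            TimepointCase(
                patient_id="x", timepoint="T9",
                mandible=FAR_MANDIBLE, landmarks=canonical_landmarks,
            )
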