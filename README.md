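# tmjvol

Landmark-based 3D temporomandibular-joint (TMJ) space volumetry and
repeated-measures time-course analysis.

Given watertight surface meshes (STL/PLY, mm) of the cranial base, a closed
glenoid-fossa region-of-interest, and the mandible at serial timepoints
(T0 = preoperative, T1/T2/T3 = follow-ups), plus a JSON file of eleven named
cranial landmarks, the package:

1. builds the anatomical reference frame — mid-axial (MAP), mid-sagittal
   (MSP) and coronal (COP) planes, per-side eminence (EmP), fossa sagittal
   (GfSP) and fossa coronal (GfCP) planes — from the landmarks;
2. superimposes each follow-up scan onto baseline with a least-squares
   3-landmark rigid fit (N, PoR, Ba), optionally refined by ICP over the
   cranial region;
3. voxelizes the fossa ROI, keeps the space superior to the eminence plane
   (`Vgf`), removes the superimposed mandibular condyle (`Vjs`), and
   partitions the joint space into anterior/posterior (`Vajs`/`Vpjs`, by
   GfCP) and medial/lateral (`Vmjs`/`Vljs`, by GfSP) compartments;
4. fits a repeated-measures marginal model (cell-means per visit,
   unstructured 4x4 covariance, REML, missing-at-random likelihood for the
   partially observed T1 visit) with Bonferroni-adjusted pairwise
   contrasts, and renders results tables;
5. generates synthetic data: a geometric sagging-phantom series with known
   ground truth, and long-format longitudinal volume records with the
   study's correlation and missingness structure.

A 2D cephalometric utility implements the mandibular-prognathism rule
(pogonion more than 1 mm anterior to the nasion perpendicular on the
Frankfort horizontal).

## CLI

```bash
# reference planes from a landmark file
tmjvol planes --landmarks lm.json --out frame.json

# measure one scan against baseline (case JSONs reference mesh files)
tmjvol measure --t0-case T0_case.json --case T1_case.json \
    --side R --h 0.3 --out volumes.csv

# repeated-measures table for one outcome
tmjvol stats --records volumes_long.csv --outcome Vjs --out table.csv

# synthetic data
tmjvol simulate phantom --out-dir cases/ --seed 1
tmjvol simulate records --out volumes_long.csv --seed 1
```

Landmark JSON is `{"N": [x,y,z], "OrR": ..., "OrL": ..., "PoR": ...,
"PoL": ..., "Ba": ..., "Cg": ..., "EmR": ..., "EmL": ..., "GfR": ...,
"GfL": ...}` in mm. A case JSON names the mesh/landmark files of one scan:

```json
{"patient_id": "p1", "timepoint": "T1",
 "mandible_mesh": "T1_mandible.stl", "cranial_mesh": "T1_cranial.stl",
 "landmarks": "T1_landmarks.json", "rois": {"R": "T0_fossa_R.stl"}}
```

(`rois` is required on the baseline case only.)

## Python API

```python
from tmjvol import (
    PhantomSpec, make_phantom_series, measure_series,
    simulate_longitudinal_records, SimSpec,
    fit_time_course, pairwise_contrasts, make_results_table,
)

series = make_phantom_series(PhantomSpec(seed=1))
volumes = measure_series(series.cases, side="R", h=0.3)

records = simulate_longitudinal_records(SimSpec(seed=1))
fit = fit_time_course(records, "Vjs")
table = make_results_table(fit, pairwise_contrasts(fit))
```

Direction conventions (recorded in frame output): superior = MAP normal
toward Cg, anterior = COP normal toward N, lateral = MSP normal toward the
side's Gf.  Voxel centers exactly on GfCP/GfSP are assigned to the
anterior/medial bin deterministically.  Default voxel pitch is 0.3 mm.

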