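# rsakit

A Python toolkit for **radiostereometric analysis (RSA)** and **CT-RSA**
implant-migration measurement: stereo calibration from a calibration
cage, rigid-body migration computation with all standard metrics and
conventions, measurement-precision analysis from double examinations,
phantom accuracy experiments, and study reporting with quality gating,
flow accounting and a reporting checklist. A synthetic phantom/study
generator produces every input the toolkit consumes, with exact ground
truth for validation.

It is written for researchers running implant-migration studies (hip,
knee, shoulder arthroplasty) and for engineers validating RSA
measurement chains.

## The measurement model

Tantalum markers (Ø 0.5–1 mm) implanted in bone and prosthesis define
two rigid bodies. Two simultaneous roentgen projections are calibrated
from a cage with *fiducial* markers (defining the detector-plane mapping
and the global coordinate system) and *control* markers (locating the
two roentgen foci by least-squares ray intersection); each marker is
triangulated as the midpoint of the common perpendicular between its two
back-projected rays.

Migration of the prosthesis relative to the bone between a baseline
examination and a follow-up is computed in two steps:

1. align the follow-up bone markers onto the baseline bone markers with
   the least-squares rigid superposition **T₁** (SVD of the centered
   cross-covariance, det +1 enforced), removing patient repositioning;
2. the rigid transform **T₂** carrying the baseline prosthesis markers
   onto the T₁-transformed follow-up prosthesis markers *is* the
   migration.

T₂ is decomposed in a per-patient migration coordinate system (origin at
the geometric center of the prosthesis markers at baseline; axes X
medial, Y superior, Z anterior in the right-side convention) into
translations (t_x, t_y, t_z) in mm and body-fixed XYZ Euler rotations
(r_x, r_y, r_z) in degrees, with the summary norms

- **TT** = ‖t‖ (total translation), **TR** = ‖r‖ (total rotation, valid
  for rotations < 5°),
- **MTPM** = max over evaluated points (markers and fictive points) of
  the displacement norm under T₂ — the maximum total point motion.

Quality of every fit is gauged by **ME**, the RMS marker residual after
superposition (stability of the markers; limit 0.35 mm), and **CN**, the
condition number σ₁/σ₃ of the centered marker configuration
(collinearity; limit 120). Results passing both limits form the
*concise* dataset; the *complete* dataset retains everything for the
mandated dual analysis. Precision is estimated from same-day *double
examinations*, whose true motion is zero, as the per-outcome mean (bias)
and SD (random error).

## Worked example

`examples/03_migration_metrics.py` implants a 0.3 mm subsidence and a 1°
rotation about the superior axis, repositions the patient arbitrarily
between the examinations, and recovers:

```
translations (tx, ty, tz) mm : [-0.  -0.3  0. ]
rotations    (rx, ry, rz) deg: [ 0.  1. -0.]
TT 0.300 mm | TR 1.000 deg | MTPM 0.477 mm at point p3
left side converted to right-side convention: tx -0.000 -> 0.000, ry 1.000 -> -1.000
second-year interval migration: ty -0.150 mm, ry 0.500 deg
```

t_y = −0.3 mm is the subsidence and r_y = 1° the applied rotation — the
bone alignment removed the repositioning exactly. MTPM (0.477 mm)
exceeds TT because the rotation moves peripheral markers farther than
the geometric center. The left-side result has t_x, r_y, r_z negated
before any group aggregation, and the second-year interval is obtained
by subtracting the 12-month from the 24-month migration.

The other scripts in `examples/` each demonstrate one capability:
rigid fitting and ME/CN (`01`), cage calibration and triangulation
(`02`), double-examination precision and sample size (`04`), the phantom
accuracy experiment and Bland–Altman comparison (`05`), and a full
two-arm study with quality gating, outcome tables, flow accounting and
the reporting checklist (`06`).

A thin CLI covers the same pipeline from the shell:

```
rsakit simulate --scenario scenario.yaml --out-dir study/
rsakit migrate --exams study/exams.csv --manifest study/manifest.json --out results.csv
rsakit precision --exams study/exams.csv --manifest study/manifest.json --out precision.csv
rsakit report --results results.csv --manifest study/manifest.json --out-dir report/
```

## Scope

Marker-based computation only: marker detection in images, model-based
(contour-matching) pose estimation, CT image registration and DICOM
parsing are out of scope. CT-RSA support covers coordinates already
expressed in the DICOM LPS frame plus acquisition-metadata validation.
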