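# Methods

This note documents the models, conventions, numerical choices and
limitations behind rsakit, in the order of the measurement chain.

## Rigid-body fitting

Given corresponding marker positions in two examinations, the rigid
motion minimizing the sum of squared residual distances is computed in
closed form: with centroids removed, the rotation is V·diag(1, 1, d)·Uᵀ
from the SVD U·Σ·Vᵀ of the (optionally weighted) cross-covariance
matrix, with d = sign(det(V·Uᵀ)) forcing a proper rotation — physical
marker sets cannot mirror, so reflections are never returned. Weights
are accepted per marker but default to uniform; the toolkit performs
unweighted fits everywhere. Orthonormality of accepted rotation matrices
is enforced to 1e-6 (inputs) and produced to machine precision.

**ME** (mean error of rigid-body fitting) is the RMS of the residual
marker distances after superposition, in mm. It is zero exactly for
congruent sets and is invariant under a common rigid motion of both
sets.

**CN** (condition number) is σ₁/σ₃ of the centroid-centered marker
position matrix. Two scaling modes exist because the customary limit of
120 is quoted with a 1/mm unit that no dimensionless ratio can carry:
`dimensionless` (the default, with the limit applied to σ₁/σ₃ directly)
and `per_mm` (σ₁/σ₃ divided by the configuration half-extent). The limit
is applied to whichever mode the configuration selects. Note one
consequence of the σ₁/σ₃ definition: an exactly planar configuration —
including every 3-marker body — has σ₃ = 0 and hence infinite CN, even
though planarity does not make the fit ill-posed. The fit therefore
rejects only *collinear* references (σ₂/σ₁ < 1e-9, the true degeneracy)
and reports the CN as-is; studies using 3-marker bodies should gate on
ME and marker count rather than CN.

## Euler decomposition and summary norms

Rotations are decomposed in the body-fixed (intrinsic) XYZ sequence, in
degrees, with the round trip exact to 1e-9° away from gimbal lock. At
ry = ±90° the decomposition is not unique; rz = 0 is returned by
convention and a flag is set. Positive rotation is right-handed
(counterclockwise looking down the axis toward the origin). TT and TR
are the Euclidean norms of the three translation/rotation components; TR
additionally carries a validity flag when any component or the norm
exceeds 5°, beyond which the Pythagorean summary of rotations is not
meaningful.

## Stereo calibration and triangulation

The detector is modelled as flat; the mapping from 2D detector
coordinates to the fiducial plane is a projective homography fitted by
normalized DLT on ≥ 4 fiducials (an affine-only fallback hook exists in
the design but a full homography subsumes it; no lens/film distortion
model is included). The focus is the least-squares intersection point of
the rays through each control marker (≥ 2) and its mapped image point;
the reported calibration quality is the RMS re-projection residual of
the controls on the plane, which sits at the scale of the detector
noise, with a warning above 0.5 mm. Triangulation returns the midpoint
of the common perpendicular between the two focus-to-image rays and the
crossing-line distance as per-point QC; rays within 1° of parallel are
refused. Correspondence between detections and marker identities is
assumed given — marker detection and matching in pixel data are out of
scope.

Uniplanar (≈ 40° between beams) and biplanar (≈ 90°) setups differ only
in cage layout; one code path serves both.

## Migration

The two-step procedure (bone alignment, then prosthesis residual
transform) makes the result invariant to patient repositioning between
examinations, verified to 1e-9 in noiseless tests. The migration
coordinate system defaults to origin at the centroid of the migrating
body's baseline markers with axes equal to the global (cage) frame —
anatomic when the patient is aligned with the cage: X medial, Y
superior, Z anterior for a right-sided implant; custom origins and
orthonormal axes are accepted and must be reused across a patient's
follow-ups. Left-sided results are converted to the right-side
convention (t_x, r_y, r_z negated) before aggregation.

MTPM is evaluated over the migrating body's baseline markers plus any
configured fictive points; a persistent fictive-point set per prosthesis
model keeps the evaluated set consistent across timepoints. Ties are
broken by lexicographic point id. For a pure translation MTPM equals TT
for every point set; MTPM (unlike the signed components) is invariant
under reorientation of the migration frame.

Interval migration (e.g. the second postoperative year) is the
component-wise difference of the two migrations relative to the common
baseline, with TT/TR recomputed from the differences and MTPM from the
differenced point-motion vectors. Subtraction of Euler components is
only approximate for large rotations, so a flag is set when either TR
exceeds 5°; an exact transform-composition alternative
(T_late ∘ T_early⁻¹) can be built from the stored transforms when
needed.

RSA global (X left, Y superior, Z anterior) and DICOM LPS (X left, Y
posterior, Z superior) frames are interconverted by the fixed proper
axis permutation sharing the left axis.

## Quality gating and statistics

All threshold comparisons are inclusive (a value exactly at a limit
passes), since the limits are phrased as acceptable upper bounds; this
includes the CT-RSA slice-thickness (1.0 mm) and pixel-size (0.5 mm)
recommendations. Defaults: ME ≤ 0.35 mm, CN ≤ 120, ≥ 3 markers,
detector ≥ 150 DPI and ≥ 8 bits, double examinations for ≥ 25% of
patients, scheduling windows ±14 days before 12 months and ±10% of the
target from 12 months, baseline within 14 days of surgery. An optional
gate exception accepts CN above the limit when ≥ 4 stable (low-ME)
markers are present, retaining the result with a flag. The gate always
returns both the concise (passing) and complete datasets, with
machine-readable exclusion reasons that feed the flow report.

Double-examination bias/precision and phantom trueness/precision use
the sample SD (n−1 denominator). Group summaries default to mean and
95% CI of the mean via the t-distribution; mean ± SD and median/IQR are
explicit style flags, not triggered by any automatic normality test.
Between-group differences use Welch's CI. Bland–Altman limits of
agreement are bias ± 1.96·SD of the paired differences.

The sample-size calculation is the standard two-sample normal
approximation n = 2(z₁₋α/2 + z₁₋β)²·sd²/Δ² per group, rounded up, then
inflated by 1/(1 − dropout). The post-test revision risk is the Bayes
odds update by the likelihood ratio of the continuous-migration
classification (LR⁺ = sens/(1−spec), LR⁻ = (1−sens)/spec); with an
uninformative test the posterior equals the prior. The classification
threshold itself is study-specific and deliberately has no default.

## Synthetic data generator

The generator is the toolkit's validation instrument and emulates:

* a two-layer calibration cage (fiducial grids in the detector plane,
  controls in a layer between plane and focus, foci at 1 m) — a
  plausible standard layout, since real cage geometries vary and are
  proprietary;
* marker configurations sampled in an ellipsoid whose anisotropy knob
  drives CN monotonically from well-dispersed to collinear;
* central projection with additive isotropic 2D Gaussian detector noise
  and Bernoulli occlusion per marker and image;
* micro-manipulator phantom runs whose applied poses are exact by
  construction, trivially satisfying the requirement of a gold standard
  an order of magnitude better than the assessed method (default grid:
  0.5 mm translations and 1° rotations about each axis plus one combined
  pose; 0.05 mm detector noise);
* longitudinal studies on the recommended schedule (baseline ≤ 14 days;
  6 weeks, 3/6/12/24 months with small day jitter): per-patient
  migration along a fixed direction with either a plateau course
  M·(1 − e^(−t/τ)), τ = 90 days, or a linear continuous course (rate per
  year) — quantitative forms chosen for the qualitative
  stabilizing/continuous categories; paired rotation about a fixed axis;
  per-exam patient repositioning (≤ 5°, ≤ 15 mm; identity at baseline,
  where the patient defines the migration frame); same-day double
  examinations for the configured fraction (default 25%); optional
  cumulative per-marker Gaussian drift (marker instability, which grows
  ME), occlusion and per-timepoint dropout.

Study examinations carry noise applied directly to the 3D marker
coordinates (default 0.05 mm per component, the scale of RSA precision);
the full projection→calibration→triangulation chain is exercised by the
phantom experiment, where detector noise of 0.05 mm propagates to ~0.05
mm translation and ~0.2° rotation SDs in the uniplanar geometry. All
randomness flows from a single seed; identical seeds give byte-identical
outputs.

What the generator does **not** emulate: physics-based X-ray rendering,
scatter and detector blur, bone remodeling, real marker-detection
failure modes, or correlated repositioning habits of radiographers.
Passing tests therefore demonstrate correctness of the computational
chain and statistics under the stated noise model, not clinical
performance of any imaging hardware.

## Problem sizes used in verification

The bundled verification runs use 200 random fit instances (n ≤ 10
markers), 100 simulated double-examination pairs, and 100 phantom
replicates of a 7-pose grid (700 migrations through the full stereo
chain); these sizes give sampling error comfortably below the assertion
tolerances while keeping a full run in the tens of seconds.

## Known limitations

* CN semantics for planar/3-marker bodies (see above).
* Interval MTPM from differenced point motions requires overlapping
  evaluated point sets; disjoint sets yield an empty interval MTPM.
* The checklist can only auto-derive items computable from the data;
  manuscript-level items (title wording, surgeon counts, revision
  narratives) must be supplied in the study configuration.
* No mixed-model longitudinal inference is included; export the results
  table to the statistics environment of choice for that analysis.
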