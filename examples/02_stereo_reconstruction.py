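"""Calibration-cage stereo calibration and 3D marker reconstruction.

Builds the synthetic uniplanar setup (two roentgen foci at ~40°, cage
with fiducial and control markers), projects a handful of bone markers
onto both detectors with 0.05 mm noise, calibrates each image from the
cage detections alone, and triangulates the markers back to 3D.
"""

import numpy as np

from rsakit.calibration import calibrate_image, reconstruct_markers
from rsakit.phantom import gen_marker_config, make_setup, project_markers

rng = np.random.default_rng(1)
setup = make_setup("uniplanar")

markers = {
    f"m{i}": p
    for i, p in enumerate(gen_marker_config(5, 30.0, rng=rng) + setup.marker_center)
}
det_a = project_markers(markers, setup, "A", noise_sd=0.05, rng=rng)
det_b = project_markers(markers, setup, "B", noise_sd=0.05, rng=rng)

geom_a = calibrate_image(setup.cage, det_a)
geom_b = calibrate_image(setup.cage, det_b)
print(f"estimated focus A (mm): {np.round(geom_a.focus, 1)}  (true {setup.foci['A']})")
print(f"control re-projection residual A: {geom_a.control_ray_residual_mm:.4f} mm")

recon = reconstruct_markers(geom_a, geom_b, det_a, det_b, marker_ids=sorted(markers))
for mid in sorted(markers):
    err = np.linalg.norm(recon.positions[mid] - markers[mid])
    print(f"{mid}: 3D error {err:.4f} mm, crossing-line distance "
          f"{recon.crossing_distance_mm[mid]:.4f} mm")
print()
print("The crossing-line distance (gap between the two back-projected rays)")
print("is the per-marker reconstruction quality check; both it and the 3D")
print("error sit at the scale of the injected 0.05 mm detector noise.")
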