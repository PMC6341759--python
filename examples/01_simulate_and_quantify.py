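"""Simulate an aqueduct PC-MRI scan and quantify its CSF hydrodynamics.

Builds a synthetic cardiac-gated scan (8 mm^2 aqueduct ROI, V_enc 17.8
cm/s, 124.5 uL designed stroke volume, peak caudal flow at 32.7% of the
cycle), runs the full measurement chain — correlation-map segmentation,
eddy-current correction, flow integration — and compares the estimates
against the known ground truth.
"""

import numpy as np

from csfpulse import (
    eddy_correction,
    flow_waveform,
    hydrodynamic_metrics,
    phase_to_velocity,
    segment_roi,
    simulate,
)
from csfpulse.pipeline import auto_static_mask
from csfpulse.segmentation import dice

series, truth = simulate("aqueduct", seed=42)
print(f"series: {series.shape[0]}x{series.shape[1]} voxels, "
      f"{series.n_frames} frames, V_enc {series.venc_cm_s} cm/s, "
      f"{series.bpm:.1f} BPM")

# 1. segment the CSF region from magnitude + temporal correlation
roi = segment_roi(series, threshold=0.6)
print(f"segmented ROI: {roi.n_voxels} voxels = {roi.area_mm2:.1f} mm^2 "
      f"(Dice vs truth {dice(roi, truth.mask):.3f})")

# 2. remove the static-tissue background phase (eddy currents)
static = auto_static_mask(series.shape[:2],
                          exclude=roi.mask | (series.magnitude.mean(axis=2) > 100))
vel = eddy_correction(phase_to_velocity(series), static, flow_roi=roi)
print(f"background offset removed: {vel.correction_offset_cm_s:.2f} cm/s "
      f"(designed {0.3 / np.pi * series.venc_cm_s:.2f})")

# 3. integrate flow over the ROI and derive the metric set
q = flow_waveform(vel, roi)
m = hydrodynamic_metrics(q, vel, roi)
print(f"caudal max velocity : {m.caudal_max_velocity_cm_s:6.1f} cm/s")
print(f"caudal mean flow    : {m.caudal_mean_flow_ml_s:6.2f} mL/s (conditional mean)")
print(f"stroke volume       : {m.sv_bradley_ul:6.1f} uL (Bradley)  "
      f"{m.sv_bateman_ul:.1f} uL (Bateman)")
print(f"designed SV         : {truth.true_metrics.sv_bradley_ul:6.1f} uL")
# Bradley SV averages the caudal and cranial lobe volumes; for the
# designed zero-net waveform the two definitions nearly coincide.
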