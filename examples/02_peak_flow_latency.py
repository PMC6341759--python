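"""Estimate the Peak Flow Latency (PFL) of a simulated scan.

PFL is the percent of the cardiac cycle at which caudal CSF flow peaks
(the waveform minimum under the caudal-negative convention).  The
estimator erodes the ROI boundary, averages the remaining voxels, keeps
the top 25% by correlation, and upsamples the 30-frame reference with a
degree-6 polynomial to 1000 samples.
"""

from csfpulse import PFLConfig, compute_pfl, phase_to_velocity, simulate

series, truth = simulate("aqueduct", seed=7, noise_sd_phase_rad=0.0,
                         noise_sd_magnitude=0.0, static_phase_offset_rad=0.0)
vel = phase_to_velocity(series)

res = compute_pfl(vel, truth.mask)
print(f"designed latency : {100 * truth.true_pfl:.1f}% of cycle")
print(f"estimated PFL    : {res.pfl_percent:.1f}%  "
      f"({res.n_voxels_used} voxels in the final reference)")

# without the polynomial fit the estimate is quantized at 100/30 = 3.3%
no_fit = compute_pfl(vel, truth.mask, PFLConfig(fit_enabled=False))
print(f"no-fit PFL       : {no_fit.pfl_percent:.1f}%  (discrete frame argmin)")
# the fit recovers sub-frame timing: its error should be well under the
# 3.3% frame spacing, while the no-fit value snaps to the frame grid
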