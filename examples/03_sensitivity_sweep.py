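"""Map PFL estimator sensitivity over fit degree x voxel removal.

The PFL depends on two tunables: the polynomial degree and the fraction
of low-correlated voxels removed before averaging.  This sweep computes
the between-cohort Mann-Whitney p-value in every cell for two small
synthetic cohorts whose designed latencies differ, plus a no-fit row.
High degree + aggressive removal overfits individual voxel noise and
destroys the group difference — visible as the p-values degrading toward
the bottom-right of the grid.
"""

import numpy as np

from csfpulse import phase_to_velocity, sensitivity_sweep, simulate

rng = np.random.default_rng(0)
cohorts = {}
for name, n, mean_lat in (("short_latency", 8, 0.245), ("long_latency", 8, 0.340)):
    pairs = []
    for _ in range(n):
        lat = float(np.clip(rng.normal(mean_lat, 0.02), 0.05, 0.9))
        series, truth = simulate("aqueduct", seed=int(rng.integers(2**31)),
                                 peak_caudal_latency=lat)
        pairs.append((phase_to_velocity(series), truth.mask))
    cohorts[name] = pairs

grid, _ = sensitivity_sweep(cohorts["short_latency"], cohorts["long_latency"],
                            degrees=(4, 6, 8, 10),
                            removal_fractions=(0.25, 0.75, 0.95))
print("two-sided Mann-Whitney p-values (rows: fit degree, cols: % voxels removed)")
print(grid.round(4))
print("\nCells below 0.05 detect the designed latency difference; the "
      "no-fit row is frame-quantized and the (high degree, 95%) corner is "
      "noise-dominated.")
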