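# Methods

## Signal model and conventions

A PC-MRI series is a magnitude stack and a phase stack over one cardiac
cycle (30 uniformly spaced frames by default, idealized retrospective
gating).  Phase encodes through-plane velocity linearly, v = (φ/π)·V_enc
with φ ∈ (−π, π]; velocities beyond ±V_enc wrap (alias).  Caudal flow is
negative everywhere in the package, so "peak caudal flow" is a waveform
minimum.  Volumetric flow is reported in mL/s using
1 cm/s · 1 mm² = 0.01 mL/s; cycle integrals use the trapezoid rule with
periodic closure (frame N wraps to frame 0).  Stroke volumes are in µL
per cycle.

## Synthetic scan generator

The generator emulates the two acquisitions the analysis targets; its
defaults are the study conditions, not tuning knobs.

**Flow waveform.** A truncated Fourier series (3 harmonics by default).
Construction: a piecewise time-warped sine whose negative (caudal) lobe
occupies a fraction `caudal_fraction` of the cycle (default 0.45 — the
systolic lobe is slightly narrower than the diastolic one), each lobe
scaled so its time integral equals the designed lobe volume; the curve is
projected onto the leading harmonics, the DC term pinned analytically so
the net volume is exact, and the band-limited curve circularly shifted so
its minimum sits at the requested latency (two corrective passes on a
2^16-point grid).  Because the result is band-limited below the frame
Nyquist, the 30-frame periodic trapezoid integral of the full cycle is
exact; lobe-wise integrals carry only the kink-discretization error
(< 0.2% at 30 frames, see the quadrature oracle test).

**Scenes.** The ROI is a rasterized ellipse (optionally blob-perturbed)
on a square voxel grid.  Spatial velocity profiles: *plug* (uniform) or
*blunted parabolic* (1 − d², floored at 0.25 of the peak — oscillatory,
Womersley-regime flow never develops the zero-wall-velocity Poiseuille
profile at voxel resolution).  Profile weights are normalized so the
ROI-summed flow reproduces the input waveform exactly in the noise-free
limit.  Presets:

| | aqueduct | cistern |
|---|---|---|
| grid / spacing | 32×32 @ 0.625 mm | 48×48 @ 0.625 mm |
| ROI area | 8.0 mm² (ellipse) | 58.6 mm² (blob) |
| profile | blunted parabolic (channel flow) | plug (piston-like bulk motion) |
| V_enc | 17.8 cm/s | 9.7 cm/s |
| heart rate | 69.2 BPM | 66.9 BPM |
| stroke volume | 124.5 µL | 293.5 µL |
| peak caudal latency | 32.7% | 24.5% |
| artery confound | — | 12 mm², leads CSF by 5%, peak 1.5·V_enc |

These choices make the derived quantities land where cohort medians put
them (e.g. the aqueduct preset's peak caudal voxel velocity is ≈ 12 cm/s).

**Confounds.** A constant phase offset (default 0.3 rad) is added to
*every* voxel — the eddy-current/accumulated-phase surrogate; applying it
globally is what makes subtraction of a static-region mean an exact
correction.  Gaussian phase noise (reference level 0.1·π rad SD per
voxel-frame) and magnitude noise are seeded and reproducible.  Flow voids
attenuate the *magnitude* of a configurable fraction of ROI boundary
voxels (phase untouched): voids are a magnitude-segmentation failure
mode, which is exactly what the correlation step is meant to rescue.  The
cistern's arterial region carries the CSF waveform's shape, leads it by
5% of the cycle, and exceeds V_enc by design so aliasing handling is
exercised; it is disjoint from the CSF ROI and excluded from ground
truth.

**What the generator does not model** — and hence what passing tests do
not demonstrate about clinical data: partial-volume mixing at the ROI
boundary, gating jitter and beat-to-beat variability, respiratory
modulation, through-plane angulation error, k-space/MR physics (Rician
magnitude statistics, ghosting), vendor phase scaling.  Recovery results
here bound algorithmic error, not scanner physics.

## Segmentation

Otsu thresholding of the temporal-mean magnitude (Canny + fill behind a
config switch) restricted to an optional search window, largest
4-connected component; frame-wise mean *velocity* waveform over that
mask; per-voxel Pearson correlation against it (affine-invariant, hence
robust to per-voxel gain); threshold r\* ≥ 0.6 by default, largest
component again.  Zero-temporal-variance voxels have no defined
correlation and are excluded rather than treated as r = 0.  The exclusion
mask is an input (an arterial footprint would come from a TOF
acquisition, which is out of scope).  4-connectivity is used for both
components and erosion, everywhere.  The r\* value and edge operator are
deliberate defaults, not protocol facts: the underlying protocol is
semi-automated and operator-tuned.

## Hydrodynamic metrics

Directional lobe volumes come from the periodic trapezoid integral of
min(q, 0) and max(q, 0).  Bradley SV is their mean; Bateman SV is the
caudal (systolic) lobe volume — the "peak portion" of the curve; for
zero-net waveforms they agree to a few percent at 30 frames.  Max
velocity is the single most extreme per-voxel value in the ROI per
direction (an ROI-mean reading would be several-fold smaller than the
values such tables report).  Directional mean flow defaults to the
*conditional* mean of |q| over frames of that sign (numerically
SV/lobe-duration): with ~124.5 µL per cycle and a ~0.39 s caudal lobe
this is ≈ 0.32 mL/s, matching the scale on which these values are
conventionally tabulated; the whole-cycle rectified mean is available via
`mean_flow_convention="rectified"`.  Both mL/s and mL/min fields are
populated so units are never implicit.  A one-signed waveform zeroes the
absent direction's metrics and sets a flag instead of raising.

## Eddy-current correction

The scalar mean velocity over (static mask × all frames) is subtracted
from every voxel and frame.  Exact for a constant offset, idempotent, and
recorded on the field.  The static region must not intersect the flow
ROI (checked when the ROI is supplied).  `auto_static_mask` picks a
static block automatically for pipeline runs; nothing beyond the scalar
offset (no polynomial background field) is fitted.

## Peak flow latency

Stages: boundary erosion (default 1 iteration, with a flagged fallback to
the uneroded mask if erosion would empty it) → voxel-mean intermediate
reference → Pearson ranking of voxels against it → mean of the top
`keep_fraction` (default 25%, count = ⌈k·n⌉, minimum 1, stable
index-order tie-break) → ordinary least-squares polynomial fit (degree 6)
on normalized time using numpy's stabilized domain mapping, evaluated at
1000 uniform points; PFL = 100·argmin, earliest minimum on ties.  The
polynomial is aperiodic by design (matching the measurement protocol), so
minima at the cycle endpoints are flagged (`edge_minimum`) rather than
hidden.  With the fit disabled the estimate reduces exactly to the
discrete frame argmin (quantized at 100/30 ≈ 3.3%).  The fit is applied
to the voxel-mean velocity waveform; a flow-weighted variant would scale
voxels by area, which for a uniform grid differs only by a constant and
leaves the argmin unchanged.  Latency comparisons require ECG gating
(frame 0 = R wave); non-ECG series trigger a warning, not an error.

Numerical behaviour worth knowing: the degree-6 fit of the default
3-harmonic waveform carries a small systematic bias (≤ 0.9 percentage
points over designed latencies of 20–40%, measured noise-free); at the
reference noise level the error stays within ~2–3 points.  At the
overfitting corner of the sensitivity grid (degree 10, 95% of voxels
removed) single-voxel noise dominates and the estimate spread grows by an
order of magnitude — the failure mode the sweep exists to expose.

## Statistics

Mann–Whitney: exact permutation null by brute-force enumeration of all
C(n, n_a) rank assignments (midranks condition on observed ties) for
pooled n ≤ 12; tie-corrected normal approximation with continuity
correction (scipy) beyond.  Wilcoxon signed-rank: differences post − pre,
zeros dropped with the reduced n recorded, exact enumeration of all 2^n
sign assignments for n ≤ 15, approximation beyond.  Both report the
method used.  Degenerate inputs (identical pooled values; all-zero
differences) return p = 1 with a flag.  Empirical type-I error of the
n=15-vs-5 asymptotic path is ≈ 4–5% at nominal 5% (checked over 2000
null pairs).  Summaries use type-7 linear-interpolation quantiles for the
IQR.  No multiple-testing correction is applied by default (matching the
reporting convention the tables follow); a Holm option exists.  Report
star thresholds are explicit per table (\* p<0.05 with \*\* p<0.001 or
p<0.01), never guessed.

## Problem sizes

The test suite and acceptance script use the presets at full design size
(30-frame series on 32×32/48×48 grids), 20 seeds per recovery check, 50
replicates for the sensitivity-sweep power measurement, and 2000 null
cohort pairs for the type-I check — small enough to run in seconds to a
few minutes on a single CPU, large enough that Monte-Carlo error is well
below the tolerances being asserted.

## Known limitations

- The correlation threshold is fixed per run; subjects with very low
  stroke volume (velocities comparable to phase noise) can segment to a
  fragment, which in practice is what the semi-automated protocol's
  operator tuning addresses.
- Bradley/Bateman lobe integrals rectify the noisy waveform, giving a
  small positive bias and a per-seed standard error of a few percent at
  the reference noise level; SV acceptance is therefore judged on the
  across-seed mean.
- No absolute time-to-peak in milliseconds (latency is a cycle fraction
  by construction), no DICOM ingestion, no TOF processing, no manual
  mask editing.
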