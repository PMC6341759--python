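# csfpulse

Quantification of pulsatile cerebrospinal-fluid (CSF) flow from cine
phase-contrast MRI (PC-MRI), aimed at hydrocephalus research: the
hyperdynamic aqueductal flow seen in normal-pressure hydrocephalus (NPH),
its normalization after shunt treatment, and the redistribution of CSF
pulsatility between the cerebral aqueduct and the prepontine cistern.

The package is a library first (importable API + `examples/`), with a thin
`csfpulse` command-line layer for shell-driven runs.  Because clinical
PC-MRI series are rarely shareable, it ships a synthetic scan generator
with exact ground truth, so every stage of the measurement chain is
testable end to end without any patient data.

## What it computes

A cardiac-gated PC-MRI acquisition yields a magnitude and a phase stack
(rows × cols × 30 frames).  Phase encodes through-plane velocity via the
velocity-encoding parameter `V_enc`:

    v = (φ / π) · V_enc        φ ∈ (−π, π],  |v| > V_enc aliases (wraps)

Caudal flow (toward the spine, systolic) is negative by convention.

- **Segmentation** — semi-automated, three steps: an edge/threshold mask of
  the temporal-mean magnitude image, a reference waveform averaged over
  that mask, and a per-voxel Pearson correlation map against the reference,
  thresholded (default r\* = 0.6) and reduced to the largest 4-connected
  component.  The dynamic step rescues voxels whose magnitude is destroyed
  by flow voids; an externally supplied exclusion mask (e.g. a TOF-derived
  basilar-artery footprint) is honoured throughout.
- **Eddy-current correction** — the mean velocity of a static-tissue
  reference region over all 30 frames is subtracted from the whole field,
  removing the constant background phase accumulated from eddy currents.
- **Hydrodynamic metrics** — ROI area (mm²); directional peak voxel
  velocities (cm/s); directional mean flows (conditional mean of |q| over
  frames of each sign, mL/s and mL/min); stroke volume per cycle (µL) in
  two definitions: Bradley SV = (caudal lobe volume + cranial lobe
  volume)/2, Bateman SV = caudal (systolic) lobe volume; and the stroke
  volume ratio 100·ASV/cistern-SV linking the two compartments.
- **Peak flow latency (PFL)** — percent of the cardiac cycle at peak caudal
  flow: erode the ROI boundary, average voxels, keep the top 25% by
  correlation with the intermediate reference, fit a degree-6 polynomial
  and upsample 30 → 1000 samples; PFL = argmin position.  A sensitivity
  sweep maps the two tunables (degree × voxel removal) to between-cohort
  p-values.
- **Cohort statistics** — Mann–Whitney rank-sum for independent groups and
  Wilcoxon signed-rank for matched pre/post pairs (exact enumerated nulls
  for small samples, tie-corrected asymptotics beyond), with
  `median [IQR] (range)` summaries and starred report tables.

## Worked example

`python examples/01_simulate_and_quantify.py` simulates an aqueduct scan
(designed: 8 mm² ROI, V_enc 17.8 cm/s, 124.5 µL stroke volume, 69 BPM,
phase noise 0.1·π rad) and measures it:

```
series: 32x32 voxels, 30 frames, V_enc 17.8 cm/s, 69.2 BPM
segmented ROI: 20 voxels = 7.8 mm^2 (Dice vs truth 0.976)
background offset removed: 1.72 cm/s (designed 1.70)
caudal max velocity :   14.3 cm/s
caudal mean flow    :   0.30 mL/s (conditional mean)
stroke volume       :  120.1 uL (Bradley)  120.6 uL (Bateman)
designed SV         :  124.4 uL
```

The segmentation recovers the designed region to Dice 0.98, the
eddy-current estimate matches the designed offset to 0.02 cm/s, and the
Bradley stroke volume lands within ~4% of the designed 124.5 µL at this
noise level; Bradley and Bateman definitions agree because the designed
waveform has zero net flow.  The other examples cover PFL estimation
(`02`), the degree × removal sensitivity grid (`03`) and a full synthetic
cohort report (`04`).

The same chain is scriptable from the shell:

```sh
csfpulse simulate --preset aqueduct --out scan/ --seed 3
csfpulse segment  --in scan/ --out scan/mask.nii.gz
csfpulse metrics  --series scan/ --mask scan/mask.nii.gz --out scan/metrics.json
csfpulse pfl      --series scan/ --mask scan/mask.nii.gz --out scan/pfl.json
csfpulse run      --config run.yaml     # multi-stage run with manifest
```

## Layout

| path | contents |
| --- | --- |
| `src/csfpulse/synthetic.py` | PC-MRI generator: waveform family, scenes, presets, cohorts |
| `src/csfpulse/io.py` | NIfTI + JSON-sidecar series I/O, cohort tables (CSV) |
| `src/csfpulse/segmentation.py` | correlation-map ROI segmentation, erosion, Dice |
| `src/csfpulse/hydrodynamics.py` | velocity decoding, eddy correction, flows, stroke volumes |
| `src/csfpulse/latency.py` | PFL estimator and sensitivity sweep |
| `src/csfpulse/stats.py` | exact/asymptotic rank tests, summaries, cohort report |
| `src/csfpulse/pipeline.py`, `cli.py` | staged runs with manifest; thin CLI |
| `docs/methods.md` | models, conventions, parameter choices, limitations |

See `docs/methods.md` for the modelling decisions and their rationale.
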