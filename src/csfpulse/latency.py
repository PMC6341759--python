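"""Peak Flow Latency (PFL): the percent of the cardiac cycle at which
caudal CSF flow peaks.

The estimator is staged exactly as the underlying measurement protocol:

1. erode the ROI boundary (partial-volume voxels dilute the flow signal);
2. average the remaining voxels' velocity waveforms into an intermediate
   reference;
3. rank every remaining voxel by Pearson correlation against it;
4. average the top ``keep_fraction`` (default 25%) of voxels into the
   final reference waveform;
5. fit a least-squares polynomial (default degree 6) on normalized cycle
   time and upsample it from the acquired 30 frames to 1000 samples; the
   PFL is the position of the minimum (caudal = negative) in percent of
   the cycle.

With the fit disabled the estimate reduces to the discrete frame argmin,
quantized at 100/n_frames percent.  The polynomial is deliberately
aperiodic (a plain polynomial in t), so a minimum at a cycle endpoint is
flagged rather than hidden.

``sensitivity_sweep`` maps the estimator's two free parameters — fit
degree and fraction of low-correlated voxels removed — to the
between-cohort Mann-Whitney p-value, reproducing the degree x removal
sensitivity table structure, including a no-fit row.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hydrodynamics import VelocityField
from .segmentation import ROIMask, _pearson_rows, erode_boundary
from .stats import mann_whitney

__all__ = ["PFLConfig", "PFLResult", "compute_pfl", "sensitivity_sweep"]

DEFAULT_REMOVAL_FRACTIONS = (0.01, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)
DEFAULT_DEGREES = (4, 5, 6, 7, 8, 9, 10)


@dataclass(frozen=True)
class PFLConfig:
    """Tunable parameters of the PFL estimator.

    erosion_iterations : boundary erosions before averaging (default 1).
    keep_fraction : fraction of voxels retained by correlation rank
        (default 0.25, i.e. 75% of low-correlated voxels removed).
    poly_degree : degree of the least-squares fit (default 6).
    dense_samples : upsampled waveform length (default 1000).
    fit_enabled : False reduces the estimate to the discrete frame argmin.
    """

    erosion_iterations: int = 1
    keep_fraction: float = 0.25
    poly_degree: int = 6
    dense_samples: int = 1000
    fit_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.keep_fraction <= 1.0):
            raise ValueError("keep_fraction must lie in (0, 1]")
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")
        if self.erosion_iterations < 0:
            raise ValueError("erosion_iterations must be >= 0")


@dataclass
class PFLResult:
    pfl_percent: float
    reference_waveform: np.ndarray
    fitted_waveform: np.ndarray | None
    n_voxels_used: int
    flags: dict = field(default_factory=dict)


def compute_pfl(vel: VelocityField, roi, config: PFLConfig = PFLConfig()) -> PFLResult:
    """Estimate the PFL for one velocity field and ROI.

    Emits a warning when the series is not ECG-gated: pulse-oximetry
    triggers shift the cycle origin, making latencies incomparable across
    subjects.  Raises when fewer distinct frames than ``poly_degree + 1``
    are available (degenerate fit).
    """
    if getattr(vel, "gating", "ecg") != "ecg":
        warnings.warn(
            "PFL computed on a non-ECG-gated series; latencies are only "
            "comparable across ECG-gated acquisitions",
            RuntimeWarning,
            stacklevel=2,
        )
    mask = roi if isinstance(roi, ROIMask) else ROIMask(np.asarray(roi, dtype=bool))
    flags: dict = {}
    if config.erosion_iterations > 0:
        mask = erode_boundary(mask, iterations=config.erosion_iterations)
        if mask.flags.get("erosion_fallback"):
            flags["erosion_fallback"] = True

    voxels = vel.v[mask.mask, :]  # (n_vox, n_frames)
    n_vox, n_frames = voxels.shape
    intermediate = voxels.mean(axis=0)

    r = _pearson_rows(voxels, intermediate)
    r = np.nan_to_num(r, nan=-np.inf)  # undefined voxels rank last
    n_keep = max(1, math.ceil(config.keep_fraction * n_vox))
    order = np.argsort(-r, kind="stable")  # deterministic tie-break by index
    reference = voxels[order[:n_keep], :].mean(axis=0)

    times = np.asarray(vel.frame_times, dtype=float)
    if not config.fit_enabled:
        idx = int(np.argmin(reference))
        return PFLResult(
            pfl_percent=100.0 * idx / n_frames,
            reference_waveform=reference,
            fitted_waveform=None,
            n_voxels_used=n_keep,
            flags=flags,
        )

    if len(np.unique(times)) < config.poly_degree + 1:
        raise ValueError(
            f"degree-{config.poly_degree} fit needs at least "
            f"{config.poly_degree + 1} distinct frames"
        )
    poly = np.polynomial.Polynomial.fit(times, reference, config.poly_degree)
    dense_t = np.arange(config.dense_samples) / config.dense_samples
    dense = poly(dense_t)
    idx = int(np.argmin(dense))  # earliest minimum wins on exact ties
    if idx in (0, config.dense_samples - 1):
        flags["edge_minimum"] = True
    return PFLResult(
        pfl_percent=100.0 * dense_t[idx],
        reference_waveform=reference,
        fitted_waveform=dense,
        n_voxels_used=n_keep,
        flags=flags,
    )


def sensitivity_sweep(
    cohort_a,
    cohort_b,
    degrees=DEFAULT_DEGREES,
    removal_fractions=DEFAULT_REMOVAL_FRACTIONS,
    include_no_fit: bool = True,
    erosion_iterations: int = 1,
    dense_samples: int = 1000,
):
    """Between-cohort p-value grid over (fit degree, voxel removal).

    ``cohort_a`` and ``cohort_b`` are lists of ``(VelocityField, roi)``
    pairs.  Returns ``(grid, pfls)``: a DataFrame of two-sided
    Mann-Whitney p-values with one row per degree (plus ``"no_fit"`` when
    requested) and one ``"<pct>%"`` column per removal fraction, and a
    dict mapping each cell to its per-subject PFL vectors.  A subject
    whose PFL computation fails in a cell is recorded as missing there,
    never fatal.
    """
    if not cohort_a or not cohort_b:
        raise ValueError("both cohorts must be non-empty")
    if any(d < 1 or d > 12 for d in degrees):
        raise ValueError("degrees must lie in [1, 12]")

    def cell_pfls(cohort, cfg):
        out = []
        for v, roi in cohort:
            try:
                out.append(compute_pfl(v, roi, cfg).pfl_percent)
            except Exception:
                out.append(np.nan)
        return np.asarray(out)

    row_keys = list(degrees) + (["no_fit"] if include_no_fit else [])
    col_keys = [f"{round(f * 100):g}%" for f in removal_fractions]
    grid = pd.DataFrame(index=pd.Index(row_keys, name="degree"), columns=col_keys, dtype=float)
    pfls: dict = {}
    for frac, col in zip(removal_fractions, col_keys):
        keep = 1.0 - frac
        for key in row_keys:
            cfg = PFLConfig(
                erosion_iterations=erosion_iterations,
                keep_fraction=max(keep, 1e-9),
                poly_degree=key if key != "no_fit" else 6,
                dense_samples=dense_samples,
                fit_enabled=key != "no_fit",
            )
            a = cell_pfls(cohort_a, cfg)
            b = cell_pfls(cohort_b, cfg)
            pfls[(key, col)] = (a, b)
            a_ok, b_ok = a[~np.isnan(a)], b[~np.isnan(b)]
            if len(a_ok) == 0 or len(b_ok) == 0:
                grid.loc[key, col] = np.nan
            else:
                grid.loc[key, col] = mann_whitney(a_ok, b_ok).p_value
    return grid, pfls
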