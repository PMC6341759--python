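"""Semi-automated ROI segmentation from dynamic PC-MRI information.

Three steps, in order:

1. an initial magnitude-based mask (Otsu threshold of the temporal-mean
   magnitude by default, Canny edges as an alternative) restricted to an
   optional search window;
2. a reference waveform — the frame-wise mean velocity over the initial
   mask;
3. a per-voxel Pearson correlation map against that reference, thresholded
   and reduced to the largest connected component.

The dynamic (correlation) step is what rescues voxels whose magnitude is
suppressed by flow voids: their phase time course still tracks the CSF
waveform even when the magnitude step misses them.  Conventions used
throughout: 4-connectivity for components and erosion; voxels with zero
temporal variance have no defined correlation and are excluded from the
ROI (never treated as r = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure

from .hydrodynamics import phase_to_velocity
from .io import PCMRISeries

__all__ = [
    "ROIMask",
    "CorrelationMap",
    "initial_mask",
    "reference_waveform",
    "correlation_map",
    "segment_roi",
    "erode_boundary",
    "dice",
]

_STRUCT4 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity cross


@dataclass
class ROIMask:
    """Binary voxel mask on the acquisition plane.

    ``area_mm2`` is always recomputed from the current voxel count — never
    stored stale.
    """

    mask: np.ndarray
    provenance: str = "manual"  # initial | correlation_thresholded | eroded | manual
    pixel_spacing_mm: float = 1.0
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_mm2(self) -> float:
        return self.n_voxels * self.pixel_spacing_mm**2

    def __and__(self, other: "ROIMask") -> "ROIMask":
        return ROIMask(self.mask & other.mask, "manual", self.pixel_spacing_mm)


@dataclass
class CorrelationMap:
    """Per-voxel Pearson correlation with a reference waveform.

    ``r`` is NaN where undefined (zero temporal variance); ``defined``
    marks the voxels where it is valid.
    """

    r: np.ndarray
    defined: np.ndarray
    reference: np.ndarray


def dice(a, b) -> float:
    """Dice overlap 2|A^B| / (|A|+|B|) between two masks."""
    a = np.asarray(getattr(a, "mask", a), dtype=bool)
    b = np.asarray(getattr(b, "mask", b), dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


def _window_mask(shape, search_window) -> np.ndarray:
    if search_window is None:
        return np.ones(shape, dtype=bool)
    if isinstance(search_window, np.ndarray):
        return search_window.astype(bool)
    r0, c0, r1, c1 = search_window
    w = np.zeros(shape, dtype=bool)
    w[r0:r1, c0:c1] = True
    return w


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask, connectivity=1)
    if labels.max() == 0:
        return np.zeros_like(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def initial_mask(
    series: PCMRISeries,
    search_window=None,
    method: str = "otsu",
) -> ROIMask:
    """Magnitude-based candidate CSF mask (step 1).

    ``method="otsu"`` thresholds the temporal-mean magnitude;
    ``method="canny"`` detects edges on it and fills the enclosed region.
    The largest 4-connected component within the search window is kept.
    """
    mean_mag = series.magnitude.mean(axis=2)
    window = _window_mask(mean_mag.shape, search_window)
    if method == "otsu":
        fg = mean_mag > filters.threshold_otsu(mean_mag[window])
    elif method == "canny":
        span = mean_mag.max() - mean_mag.min()
        norm = (mean_mag - mean_mag.min()) / (span if span > 0 else 1.0)
        edges = feature.canny(norm, sigma=1.0)
        fg = ndimage.binary_fill_holes(edges)
    else:
        raise ValueError(f"unknown method {method!r}")
    fg = _largest_component(fg & window)
    if not fg.any():
        raise ValueError(
            "initial magnitude mask is empty; adjust the search window or "
            "the edge-detection method"
        )
    return ROIMask(fg, provenance="initial", pixel_spacing_mm=series.pixel_spacing_mm)


def reference_waveform(series: PCMRISeries, mask) -> np.ndarray:
    """Frame-wise mean velocity over the mask voxels (step 2)."""
    m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    vel = phase_to_velocity(series)
    return vel.v[m, :].mean(axis=0)


def _pearson_rows(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson r of each row of x against ref; NaN where undefined."""
    xc = x - x.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    xn = np.sqrt((xc**2).sum(axis=1))
    rn = np.sqrt((rc**2).sum())
    scale = max(np.abs(x).max(), np.abs(ref).max(), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ rc) / (xn * rn)
    undefined = (xn <= 1e-12 * scale) | (rn <= 1e-12 * scale)
    r[undefined] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def correlation_map(series: PCMRISeries, reference: np.ndarray) -> CorrelationMap:
    """Pearson correlation of every voxel's velocity series with the
    reference (step 3a).  Zero-variance voxels are flagged undefined."""
    reference = np.asarray(reference, dtype=float)
    if len(reference) != series.n_frames:
        raise ValueError("reference length must equal the frame count")
    vel = phase_to_velocity(series)
    flat = vel.v.reshape(-1, series.n_frames)
    r = _pearson_rows(flat, reference).reshape(series.shape[:2])
    return CorrelationMap(r=r, defined=~np.isnan(r), reference=reference)


def segment_roi(
    series: PCMRISeries,
    threshold: float = 0.6,
    exclusion_mask=None,
    search_window=None,
    initial_method: str = "otsu",
    erode_iterations: int = 0,
) -> ROIMask:
    """Full three-step segmentation: initial mask -> reference waveform ->
    correlation map -> threshold -> largest component.

    ``exclusion_mask`` (e.g. an externally derived arterial footprint) is
    removed before component selection, so the final ROI never intersects
    it.  ``threshold`` must lie in (0, 1); the final ROI area is
    non-increasing in it.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    init = initial_mask(series, search_window=search_window, method=initial_method)
    ref = reference_waveform(series, init)
    cmap = correlation_map(series, ref)
    window = _window_mask(series.shape[:2], search_window)
    cand = cmap.defined & (np.nan_to_num(cmap.r, nan=-2.0) >= threshold) & window
    if exclusion_mask is not None:
        cand &= ~np.asarray(getattr(exclusion_mask, "mask", exclusion_mask), dtype=bool)
    final = _largest_component(cand)
    if not final.any():
        raise ValueError(
            f"no voxels survive correlation threshold r >= {threshold}; "
            "lower the threshold or widen the search window"
        )
    out = ROIMask(
        final,
        provenance="correlation_thresholded",
        pixel_spacing_mm=series.pixel_spacing_mm,
    )
    if erode_iterations > 0:
        out = erode_boundary(out, iterations=erode_iterations)
    return out


def erode_boundary(mask: ROIMask, iterations: int = 1) -> ROIMask:
    """Morphologically erode the mask boundary (4-connectivity).

    Partial-volume contaminated boundary voxels dilute the flow signal;
    removing them sharpens waveform-based analyses.  If erosion would
    empty the mask, the pre-erosion mask is returned with the
    ``erosion_fallback`` flag set instead of failing.
    """
    m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    spacing = getattr(mask, "pixel_spacing_mm", 1.0)
    if iterations <= 0:
        return ROIMask(m, provenance="eroded", pixel_spacing_mm=spacing)
    eroded = ndimage.binary_erosion(m, structure=_STRUCT4, iterations=iterations)
    if not eroded.any():
        return ROIMask(
            m,
            provenance="eroded",
            pixel_spacing_mm=spacing,
            flags={"erosion_fallback": True},
        )
    return ROIMask(eroded, provenance="eroded", pixel_spacing_mm=spacing)
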