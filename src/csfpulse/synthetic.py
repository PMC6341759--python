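"""Synthetic cardiac-gated PC-MRI generator with known ground truth.

Emulates the two acquisitions of interest for CSF pulsatility studies:

* an *aqueduct* scan — a small (~8 mm^2) region of high-velocity pulsatile
  CSF, V_enc around 18 cm/s, 30 frames per cardiac cycle;
* a *cistern* scan — a large (~60 mm^2) CSF region at lower velocity
  (V_enc ~10 cm/s) with an adjacent high-velocity arterial confound
  (basilar artery) that may alias.

The CSF flow waveform is a truncated Fourier series (default 3 harmonics)
shaped to be biphasic with zero (or specified) net volume per cycle, an
asymmetry parameter controlling the caudal-lobe width, and its minimum
(peak caudal flow; caudal is encoded as negative) placed at a controlled
fraction of the cycle.  Velocity maps to phase as phi = pi * v / V_enc,
wrapped into (-pi, pi], so velocities beyond +/-V_enc alias exactly as in
the scanner.  A constant phase offset models accumulated phase / eddy
currents; magnitude flow voids attenuate boundary voxels of the magnitude
stack only (phase is preserved), which is what degrades magnitude-based
segmentation in real data.

Every generated series is paired with its :class:`GroundTruth` — the true
mask, waveform parameters, per-voxel peak velocities, analytic
hydrodynamic metrics and peak-flow latency — so downstream estimators can
be scored without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hydrodynamics import (
    CM_S_MM2_TO_ML_S,
    FlowWaveform,
    HydrodynamicMetrics,
    cycle_volumes_ul,
)
from .io import PCMRISeries
from .segmentation import ROIMask

__all__ = [
    "WaveformParams",
    "SceneParams",
    "ArteryParams",
    "GroundTruth",
    "FourierWaveform",
    "build_waveform_model",
    "generate_flow_waveform",
    "generate_pc_series",
    "generate_cohort",
    "GroupSpec",
    "CohortSpec",
    "aqueduct_preset",
    "cistern_preset",
    "preset",
    "DEFAULT_PHASE_NOISE_SD",
]

#: reference phase-noise level (radians) used by the presets
DEFAULT_PHASE_NOISE_SD = 0.1 * math.pi

_MAG_BACKGROUND = 40.0
_MAG_CSF = 200.0
_MAG_ARTERY = 220.0
_VOID_ATTENUATION = 0.1


@dataclass(frozen=True)
class WaveformParams:
    """Design parameters of the biphasic CSF flow waveform.

    period_s : cardiac period in seconds.
    peak_caudal_latency : fraction of the cycle in [0, 1) at which caudal
        flow peaks (the waveform minimum).
    caudal_volume_ul / cranial_volume_ul : lobe volumes in microliters per
        cycle; equal values give zero net flow.
    n_harmonics : Fourier harmonics retained (>= 1).
    caudal_fraction : fraction of the cycle occupied by the caudal lobe,
        in (0, 1); 0.5 is symmetric.
    """

    period_s: float
    peak_caudal_latency: float = 0.327
    caudal_volume_ul: float = 124.5
    cranial_volume_ul: float = 124.5
    n_harmonics: int = 3
    caudal_fraction: float = 0.45

    def __post_init__(self) -> None:
        if not self.period_s > 0:
            raise ValueError("period_s must be positive")
        if not (0.0 <= self.peak_caudal_latency < 1.0):
            raise ValueError("peak_caudal_latency must lie in [0, 1)")
        if self.caudal_volume_ul < 0 or self.cranial_volume_ul < 0:
            raise ValueError("lobe volumes must be non-negative")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if not (0.0 < self.caudal_fraction < 1.0):
            raise ValueError("caudal_fraction must lie in (0, 1)")


class FourierWaveform:
    """Continuous band-limited flow waveform q(tau), tau in [0,1), mL/s.

    One-sided complex Fourier coefficients ``c[k]``; evaluation is
    ``c0 + sum_k 2 Re(c_k exp(i 2 pi k tau))``.  Being band-limited, its
    full-cycle trapezoid integral on any uniform grid with more than
    2*n_harmonics points equals its mean exactly.
    """

    def __init__(self, coeffs: np.ndarray):
        self.coeffs = np.asarray(coeffs, dtype=complex)

    def __call__(self, tau) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        out = np.full(tau.shape, self.coeffs[0].real)
        for k in range(1, len(self.coeffs)):
            out = out + 2.0 * (
                self.coeffs[k].real * np.cos(2 * np.pi * k * tau)
                - self.coeffs[k].imag * np.sin(2 * np.pi * k * tau)
            )
        return out

    def shifted(self, delta: float) -> "FourierWaveform":
        """Return q(tau - delta) (a circular time shift)."""
        k = np.arange(len(self.coeffs))
        return FourierWaveform(self.coeffs * np.exp(-2j * np.pi * k * delta))

    def argmin(self, n_grid: int = 1 << 16) -> float:
        tau = np.arange(n_grid) / n_grid
        return float(tau[np.argmin(self(tau))])


def build_waveform_model(params: WaveformParams) -> FourierWaveform:
    """Construct the continuous waveform for the given design parameters.

    A piecewise-warped sine (caudal lobe of width ``caudal_fraction``, each
    lobe scaled to its designed volume) is projected onto the first
    ``n_harmonics`` Fourier harmonics — the DC term, hence the net volume,
    is preserved exactly by the projection — and then circularly shifted so
    that the minimum of the band-limited waveform lands on the requested
    latency.
    """
    f = params.caudal_fraction
    m = 4096
    tau = np.arange(m) / m
    s = np.where(tau < f, tau / (2 * f), 0.5 + (tau - f) / (2 * (1 - f)))
    base = -np.sin(2 * np.pi * s)
    # per-lobe amplitudes (uL/s) giving the designed lobe volumes
    a_caudal = params.caudal_volume_ul * np.pi / (2 * f * params.period_s)
    a_cranial = params.cranial_volume_ul * np.pi / (2 * (1 - f) * params.period_s)
    q_ul_s = np.where(base < 0, a_caudal * base, a_cranial * base)
    coeffs = np.fft.rfft(q_ul_s / 1000.0) / m  # mL/s
    coeffs = coeffs[: params.n_harmonics + 1].copy()
    # pin the DC term to the analytic net flow so the designed net volume
    # is exact, not subject to rasterization error
    coeffs[0] = (params.cranial_volume_ul - params.caudal_volume_ul) / (
        1000.0 * params.period_s
    )
    model = FourierWaveform(coeffs)
    if params.caudal_volume_ul == 0 and params.cranial_volume_ul == 0:
        return model
    # two corrective passes pin the dense argmin to the requested latency
    for _ in range(2):
        model = model.shifted(params.peak_caudal_latency - model.argmin())
    return model


def generate_flow_waveform(params: WaveformParams, n_frames: int) -> FlowWaveform:
    """Sample the designed waveform at ``n_frames`` uniform cycle positions.

    Returns a :class:`FlowWaveform` in mL/s (caudal negative).  The
    trapezoid net volume over the closed cycle equals
    ``cranial_volume_ul - caudal_volume_ul`` to machine precision.
    """
    if n_frames < 8:
        raise ValueError("n_frames must be >= 8")
    if n_frames <= 2 * params.n_harmonics:
        raise ValueError("n_frames must exceed twice n_harmonics")
    model = build_waveform_model(params)
    times = np.arange(n_frames) / n_frames
    wf = FlowWaveform(q=model(times), times=times, period_s=params.period_s)
    wf._params = params  # carried for ground-truth bookkeeping
    wf._model = model
    return wf


@dataclass(frozen=True)
class ArteryParams:
    """High-velocity arterial confound adjacent to the CSF region.

    The artery carries the CSF waveform's shape, leading it by
    ``latency_lead`` of a cycle, with peak velocity
    ``velocity_scale_venc * V_enc`` — values above 1 exercise aliasing.
    """

    center: tuple[int, int]
    area_mm2: float = 12.0
    velocity_scale_venc: float = 1.5
    latency_lead: float = 0.05


@dataclass(frozen=True)
class SceneParams:
    """Geometry, encoding and noise description of one synthetic scan."""

    grid_shape: tuple[int, int] = (32, 32)
    pixel_spacing_mm: float = 0.625
    roi_center: tuple[int, int] = (16, 16)
    roi_area_mm2: float = 8.0
    roi_shape: str = "ellipse"  # "ellipse" | "blob"
    roi_aspect: float = 1.3
    velocity_profile: str = "parabolic"  # "plug" | "parabolic"
    venc_cm_s: float = 17.8
    static_phase_offset_rad: float = 0.3
    artery: ArteryParams | None = None
    noise_sd_phase_rad: float = 0.0
    noise_sd_magnitude: float = 0.0
    flow_void_fraction: float = 0.0
    gating: str = "ecg"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.venc_cm_s > 0:
            raise ValueError("venc_cm_s must be positive")
        if self.noise_sd_phase_rad < 0 or self.noise_sd_magnitude < 0:
            raise ValueError("noise SDs must be non-negative")
        if not (0.0 <= self.flow_void_fraction <= 1.0):
            raise ValueError("flow_void_fraction must lie in [0, 1]")
        if self.roi_shape not in ("ellipse", "blob"):
            raise ValueError(f"unknown roi_shape {self.roi_shape!r}")
        if self.velocity_profile not in ("plug", "parabolic"):
            raise ValueError(f"unknown velocity_profile {self.velocity_profile!r}")
        if self.roi_area_mm2 / self.pixel_spacing_mm**2 < 4:
            raise ValueError("ROI must span at least 4 voxels at this spacing")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm**2


@dataclass
class GroundTruth:
    """Everything needed to score an estimator on a synthetic series."""

    mask: ROIMask
    waveform_params: WaveformParams
    per_voxel_peak_velocity_cm_s: np.ndarray
    true_metrics: HydrodynamicMetrics
    true_pfl: float  # fraction of cycle
    artery_mask: np.ndarray | None = None
    void_mask: np.ndarray | None = None
    static_phase_offset_rad: float = 0.0
    wrap_occurred: bool = False
    weights: np.ndarray | None = None


def _raster_region(
    shape: tuple[int, int],
    center: tuple[int, int],
    area_mm2: float,
    pixel_spacing_mm: float,
    aspect: float = 1.0,
    blob: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize an elliptical (optionally blob-perturbed) region.

    Returns (mask, normalized elliptical radius map) — the radius map
    drives the parabolic velocity profile.
    """
    n_target = area_mm2 / pixel_spacing_mm**2
    r_row = math.sqrt(n_target * aspect / math.pi)
    r_col = math.sqrt(n_target / (aspect * math.pi))
    rows, cols = np.indices(shape)
    dr = (rows - center[0]) / r_row
    dc = (cols - center[1]) / r_col
    d = np.hypot(dr, dc)
    if blob:
        rng = rng if rng is not None else np.random.default_rng(0)
        theta = np.arctan2(dc, dr)
        mod = np.ones(shape)
        for k in (2, 3):
            amp = rng.uniform(0.05, 0.18)
            ph = rng.uniform(0, 2 * np.pi)
            mod += amp * np.cos(k * theta + ph)
        d = d / np.maximum(mod, 0.3)
    return d <= 1.0, d


def _analytic_metrics(
    model: FourierWaveform,
    params: WaveformParams,
    n_voxels: int,
    pixel_area_mm2: float,
    peak_weight_ratio: float,
) -> HydrodynamicMetrics:
    """Ground-truth metric set from the continuous waveform (dense grid).

    ``peak_weight_ratio`` is max(w)/mean(w) of the spatial profile — the
    factor relating the ROI-mean velocity to the fastest voxel.
    """
    n = 1 << 16
    tau = np.arange(n) / n
    q = model(tau)  # mL/s
    caudal_vol, cranial_vol = cycle_volumes_ul(q, tau, params.period_s)
    area = n_voxels * pixel_area_mm2
    # ROI-mean velocity (cm/s) = q / (area * 0.01); fastest voxel scales it
    v_mean = q / (area * CM_S_MM2_TO_ML_S)
    caudal_max = float(max(0.0, -v_mean.min()) * peak_weight_ratio)
    cranial_max = float(max(0.0, v_mean.max()) * peak_weight_ratio)
    neg, pos = q[q < 0], q[q > 0]
    caudal_mean = float(np.abs(neg).mean()) if len(neg) else 0.0
    cranial_mean = float(pos.mean()) if len(pos) else 0.0
    return HydrodynamicMetrics(
        area_mm2=area,
        caudal_max_velocity_cm_s=caudal_max,
        cranial_max_velocity_cm_s=cranial_max,
        caudal_mean_flow_ml_s=caudal_mean,
        cranial_mean_flow_ml_s=cranial_mean,
        caudal_mean_flow_ml_min=caudal_mean * 60.0,
        cranial_mean_flow_ml_min=cranial_mean * 60.0,
        sv_bradley_ul=(caudal_vol + cranial_vol) / 2.0,
        sv_bateman_ul=caudal_vol,
        net_volume_ul=cranial_vol - caudal_vol,
        caudal_volume_ul=caudal_vol,
        cranial_volume_ul=cranial_vol,
    )


def generate_pc_series(
    scene: SceneParams,
    waveform: FlowWaveform,
    params: WaveformParams | None = None,
) -> tuple[PCMRISeries, GroundTruth]:
    """Render a magnitude + phase stack for a scene and flow waveform.

    The ROI voxels share the waveform's time course, spatially weighted by
    the chosen profile and normalized so the ROI-summed flow reproduces the
    input waveform exactly in the noise-free limit.  Velocity v encodes to
    phase pi*v/V_enc plus the constant eddy-current offset, then wraps into
    (-pi, pi].  Raises if the profile's fastest voxel would exceed
    2*V_enc (double-wrap makes the ground truth ambiguous).
    """
    params = params if params is not None else getattr(waveform, "_params", None)
    model = getattr(waveform, "_model", None)
    rng = np.random.default_rng(scene.seed)
    shape = scene.grid_shape
    n_frames = waveform.n_frames
    a_pix = scene.pixel_area_mm2

    roi, d = _raster_region(
        shape,
        scene.roi_center,
        scene.roi_area_mm2,
        scene.pixel_spacing_mm,
        aspect=scene.roi_aspect,
        blob=scene.roi_shape == "blob",
        rng=rng,
    )
    if not roi.any():
        raise ValueError("ROI rasterized to zero voxels")

    if scene.velocity_profile == "plug":
        w = roi.astype(float)
    else:
        # blunted parabola: oscillatory (Womersley-regime) CSF flow never
        # reaches zero wall velocity at voxel resolution
        w = np.where(roi, np.clip(1.0 - d**2, 0.25, None), 0.0)
    w_sum = w.sum()

    q = np.asarray(waveform.q, dtype=float)  # mL/s
    # v_i(t) [cm/s] = q(t)[mL/s] * 100 * w_i / (sum_w * a_pix[mm^2])
    vel_scale = 100.0 * w / (w_sum * a_pix)
    peak_v = float(np.abs(q).max() * vel_scale.max())
    if peak_v > 2.0 * scene.venc_cm_s:
        raise ValueError(
            f"peak ROI velocity {peak_v:.1f} cm/s exceeds 2*V_enc = "
            f"{2 * scene.venc_cm_s:.1f} cm/s; ground truth would double-wrap"
        )
    v = vel_scale[:, :, None] * q[None, None, :]

    artery_mask = None
    if scene.artery is not None:
        artery_mask, _ = _raster_region(
            shape,
            scene.artery.center,
            scene.artery.area_mm2,
            scene.pixel_spacing_mm,
        )
        if (artery_mask & roi).any():
            raise ValueError("artery region overlaps the CSF ROI")
        if artery_mask.any():
            ref = q / max(np.abs(q).max(), 1e-30)  # unit-peak shape
            lead_times = (waveform.times + scene.artery.latency_lead) % 1.0
            if model is not None:
                shape_t = model(lead_times) / max(np.abs(model(waveform.times)).max(), 1e-30)
            else:
                shape_t = np.interp(lead_times, waveform.times, ref, period=1.0)
            v_art = scene.artery.velocity_scale_venc * scene.venc_cm_s * shape_t
            v[artery_mask, :] = v_art[None, :]

    phi_clean = np.pi * v / scene.venc_cm_s + scene.static_phase_offset_rad
    phi = phi_clean + rng.normal(0.0, scene.noise_sd_phase_rad, size=v.shape)
    wrap_occurred = bool((np.abs(phi_clean) > np.pi).any())
    phi = np.pi - np.mod(np.pi - phi, 2 * np.pi)  # wrap into (-pi, pi]

    mag2d = np.full(shape, _MAG_BACKGROUND)
    mag2d[roi] = _MAG_CSF
    if artery_mask is not None:
        mag2d[artery_mask] = _MAG_ARTERY
    void_mask = None
    if scene.flow_void_fraction > 0:
        from scipy import ndimage

        interior = ndimage.binary_erosion(roi, structure=ndimage.generate_binary_structure(2, 1))
        boundary = np.argwhere(roi & ~interior)
        n_void = int(round(scene.flow_void_fraction * len(boundary)))
        if n_void > 0:
            pick = rng.choice(len(boundary), size=n_void, replace=False)
            void_mask = np.zeros(shape, dtype=bool)
            void_mask[tuple(boundary[pick].T)] = True
            mag2d = np.where(void_mask, mag2d * _VOID_ATTENUATION, mag2d)
    mag = np.repeat(mag2d[:, :, None], n_frames, axis=2)
    mag = np.clip(mag + rng.normal(0.0, scene.noise_sd_magnitude, size=mag.shape), 0.0, None)

    series = PCMRISeries(
        magnitude=mag,
        phase=phi,
        venc_cm_s=scene.venc_cm_s,
        pixel_spacing_mm=scene.pixel_spacing_mm,
        period_s=waveform.period_s,
        gating=scene.gating,
        seed=scene.seed,
    )

    peak_ratio = float(w[roi].max() * roi.sum() / w_sum)
    if params is not None and model is not None:
        true_metrics = _analytic_metrics(model, params, int(roi.sum()), a_pix, peak_ratio)
        true_pfl = params.peak_caudal_latency
    else:
        # fall back to the discrete samples when no design params are carried
        caudal_vol, cranial_vol = cycle_volumes_ul(q, waveform.times, waveform.period_s)
        vroi = v[roi, :]
        neg, pos = q[q < 0], q[q > 0]
        true_metrics = HydrodynamicMetrics(
            area_mm2=float(roi.sum()) * a_pix,
            caudal_max_velocity_cm_s=float(max(0.0, -vroi.min())),
            cranial_max_velocity_cm_s=float(max(0.0, vroi.max())),
            caudal_mean_flow_ml_s=float(np.abs(neg).mean()) if len(neg) else 0.0,
            cranial_mean_flow_ml_s=float(pos.mean()) if len(pos) else 0.0,
            caudal_mean_flow_ml_min=(float(np.abs(neg).mean()) if len(neg) else 0.0) * 60,
            cranial_mean_flow_ml_min=(float(pos.mean()) if len(pos) else 0.0) * 60,
            sv_bradley_ul=(caudal_vol + cranial_vol) / 2.0,
            sv_bateman_ul=caudal_vol,
            net_volume_ul=cranial_vol - caudal_vol,
            caudal_volume_ul=caudal_vol,
            cranial_volume_ul=cranial_vol,
        )
        true_pfl = float(waveform.times[np.argmin(q)])

    truth = GroundTruth(
        mask=ROIMask(mask=roi, provenance="manual", pixel_spacing_mm=scene.pixel_spacing_mm),
        waveform_params=params,
        per_voxel_peak_velocity_cm_s=np.abs(v).max(axis=2),
        true_metrics=true_metrics,
        true_pfl=true_pfl,
        artery_mask=artery_mask,
        void_mask=void_mask,
        static_phase_offset_rad=scene.static_phase_offset_rad,
        wrap_occurred=wrap_occurred,
        weights=w,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Presets: the two acquisitions of the study


def aqueduct_preset(seed: int = 0, **overrides):
    """Aqueduct-like scene + waveform: 8 mm^2 ROI, V_enc 17.8 cm/s, 69 BPM,
    124.5 uL stroke volume, peak caudal flow at 32.7% of the cycle."""
    wf_over = {k: overrides.pop(k) for k in list(overrides) if k in WaveformParams.__dataclass_fields__}
    scene_kw = dict(
        grid_shape=(32, 32),
        pixel_spacing_mm=0.625,
        roi_center=(16, 16),
        roi_area_mm2=8.0,
        venc_cm_s=17.8,
        velocity_profile="parabolic",
        static_phase_offset_rad=0.3,
        noise_sd_phase_rad=DEFAULT_PHASE_NOISE_SD,
        noise_sd_magnitude=8.0,
        seed=seed,
    )
    scene_kw.update(overrides)
    wf_kw = dict(
        period_s=60.0 / 69.2,
        peak_caudal_latency=0.327,
        caudal_volume_ul=124.5,
        cranial_volume_ul=124.5,
    )
    wf_kw.update(wf_over)
    return SceneParams(**scene_kw), WaveformParams(**wf_kw)


def cistern_preset(seed: int = 0, **overrides):
    """Prepontine-cistern-like scene + waveform: 58.6 mm^2 ROI, V_enc 9.7
    cm/s, 67 BPM, 293.5 uL stroke volume, peak caudal flow at 24.5% of the
    cycle, with a basilar-artery confound that exceeds V_enc."""
    wf_over = {k: overrides.pop(k) for k in list(overrides) if k in WaveformParams.__dataclass_fields__}
    scene_kw = dict(
        grid_shape=(48, 48),
        pixel_spacing_mm=0.625,
        roi_center=(24, 22),
        roi_area_mm2=58.6,
        roi_shape="blob",
        venc_cm_s=9.7,
        # cisternal CSF moves with the piston-like bulk motion of the
        # brainstem: a plug profile, unlike the channel flow in the aqueduct
        velocity_profile="plug",
        static_phase_offset_rad=0.3,
        artery=ArteryParams(center=(14, 34), area_mm2=12.0),
        noise_sd_phase_rad=DEFAULT_PHASE_NOISE_SD,
        noise_sd_magnitude=8.0,
        seed=seed,
    )
    scene_kw.update(overrides)
    wf_kw = dict(
        period_s=60.0 / 66.9,
        peak_caudal_latency=0.245,
        caudal_volume_ul=293.5,
        cranial_volume_ul=293.5,
    )
    wf_kw.update(wf_over)
    return SceneParams(**scene_kw), WaveformParams(**wf_kw)


_PRESETS = {"aqueduct": aqueduct_preset, "cistern": cistern_preset}


def preset(name: str, seed: int = 0, **overrides):
    """Look up a named preset; returns (SceneParams, WaveformParams)."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    return _PRESETS[name](seed=seed, **overrides)


def simulate(name_or_scene, wparams: WaveformParams | None = None, n_frames: int = 30,
             seed: int = 0, **overrides) -> tuple[PCMRISeries, GroundTruth]:
    """One-call preset simulation: ``simulate("aqueduct", seed=3)``."""
    if isinstance(name_or_scene, str):
        scene, wparams = preset(name_or_scene, seed=seed, **overrides)
    else:
        scene = name_or_scene
        if wparams is None:
            raise ValueError("wparams required when passing a SceneParams")
    wf = generate_flow_waveform(wparams, n_frames)
    return generate_pc_series(scene, wf)


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class GroupSpec:
    """One synthetic cohort group: n subjects drawn from stated distributions.

    ``distributions`` maps parameter names to ("normal", mean, sd) or
    ("fixed", value); supported parameters: ``latency`` (fraction of
    cycle), ``sv_ul``, ``area_mm2``, ``bpm``.  Draws violating physical
    bounds are truncated and recorded in the draw log.
    """

    name: str
    group: str  # pre_shunt | post_shunt | control
    n: int
    site: str = "aqueduct"  # preset name
    distributions: dict = field(default_factory=dict)
    scene_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple
    seed: int = 0
    n_frames: int = 30


_BOUNDS = {"latency": (0.0, 0.999), "sv_ul": (1.0, None), "area_mm2": (2.0, None), "bpm": (30.0, 150.0)}


def _draw(dist, rng) -> float:
    kind = dist[0]
    if kind == "normal":
        return float(rng.normal(dist[1], dist[2]))
    if kind == "fixed":
        return float(dist[1])
    raise ValueError(f"unknown distribution kind {kind!r}")


def generate_cohort(spec: CohortSpec):
    """Generate one synthetic series per subject across all groups.

    Returns ``(subjects, draw_log)`` where ``subjects`` is a list of
    ``(group_name, PCMRISeries, GroundTruth)`` and ``draw_log`` is a
    DataFrame recording every parameter draw (including truncations) for
    reproducibility.  Identical specs (including seed) reproduce
    bit-identical output.
    """
    root = np.random.SeedSequence(spec.seed)
    group_seeds = root.spawn(len(spec.groups))
    subjects = []
    log_rows = []
    for gspec, gseq in zip(spec.groups, group_seeds):
        rng = np.random.default_rng(gseq)
        subj_seeds = gseq.spawn(gspec.n)
        for i in range(gspec.n):
            overrides = dict(gspec.scene_overrides)
            row = {"group": gspec.name, "subject": i}
            for pname, dist in gspec.distributions.items():
                val = _draw(dist, rng)
                lo, hi = _BOUNDS.get(pname, (None, None))
                truncated = False
                if lo is not None and val < lo:
                    val, truncated = lo, True
                if hi is not None and val > hi:
                    val, truncated = hi, True
                row[pname], row[f"{pname}_truncated"] = val, truncated
                if pname == "latency":
                    overrides["peak_caudal_latency"] = val
                elif pname == "sv_ul":
                    overrides["caudal_volume_ul"] = val
                    overrides["cranial_volume_ul"] = val
                elif pname == "area_mm2":
                    overrides["roi_area_mm2"] = val
                elif pname == "bpm":
                    overrides["period_s"] = 60.0 / val
            seed_i = int(subj_seeds[i].generate_state(1)[0] % (2**31))
            row["scene_seed"] = seed_i
            series, truth = simulate(gspec.site, seed=seed_i, n_frames=spec.n_frames, **overrides)
            subjects.append((gspec.name, series, truth))
            log_rows.append(row)
    return subjects, pd.DataFrame(log_rows)
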