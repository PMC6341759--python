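"""Phase-to-velocity conversion, eddy-current correction and flow metrics.

Sign convention: caudal flow (toward the spine, the systolic direction) is
NEGATIVE velocity and flow throughout; "peak caudal flow" is therefore the
waveform minimum.

Units. Velocities are cm/s, ROI areas mm^2, volumetric flow mL/s (with
mL/min reported alongside), stroke volumes uL per cardiac cycle.  The one
conversion constant that matters:

    1 cm/s through 1 mm^2  =  10 mm^3/s  =  0.01 mL/s

Cycle integrals use the trapezoid rule with periodic closure: frame N wraps
back to frame 0, so a 30-frame waveform is integrated over 31 nodes
spanning exactly one period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import PCMRISeries

__all__ = [
    "VelocityField",
    "FlowWaveform",
    "HydrodynamicMetrics",
    "CM_S_MM2_TO_ML_S",
    "phase_to_velocity",
    "eddy_correction",
    "flow_waveform",
    "hydrodynamic_metrics",
    "stroke_volume_ratio",
    "cycle_volumes_ul",
]

#: 1 cm/s of velocity through 1 mm^2 of area = 0.01 mL/s of volumetric flow
CM_S_MM2_TO_ML_S = 0.01


def _mask_array(mask) -> np.ndarray:
    """Accept a bare boolean array or any object with a ``.mask`` array."""
    m = getattr(mask, "mask", mask)
    return np.asarray(m, dtype=bool)


@dataclass
class VelocityField:
    """Per-voxel velocity time series decoded from the phase stack."""

    v: np.ndarray  # rows x cols x frames, cm/s, caudal negative
    venc_cm_s: float
    pixel_spacing_mm: float
    period_s: float
    frame_times: np.ndarray
    corrected: bool = False
    correction_offset_cm_s: float = 0.0
    gating: str = "ecg"

    @property
    def n_frames(self) -> int:
        return self.v.shape[2]

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm**2


@dataclass
class FlowWaveform:
    """ROI-integrated volumetric flow over one cardiac cycle.

    ``q`` is in mL/s (caudal negative); ``times`` are normalized cycle
    positions in [0, 1).  ``fitted`` optionally carries a least-squares
    polynomial upsampling of the waveform (coefficients + dense samples).
    """

    q: np.ndarray
    times: np.ndarray
    period_s: float
    fitted: dict | None = None

    @property
    def n_frames(self) -> int:
        return len(self.q)

    def net_volume_ul(self) -> float:
        """Trapezoid net volume over one closed cycle, in microliters."""
        caudal, cranial = cycle_volumes_ul(self.q, self.times, self.period_s)
        return cranial - caudal


@dataclass
class HydrodynamicMetrics:
    """The per-series metric set: area, velocities, flows, stroke volumes.

    ``sv_bradley_ul`` is the mean of the caudal and cranial lobe volumes;
    ``sv_bateman_ul`` is the systolic (caudal) lobe volume alone.  For
    zero-net pulsatile flow the two nearly coincide.  Directional mean
    flows are conditional means of |q| over the frames of that sign by
    default (see :func:`hydrodynamic_metrics`).
    """

    area_mm2: float
    caudal_max_velocity_cm_s: float
    cranial_max_velocity_cm_s: float
    caudal_mean_flow_ml_s: float
    cranial_mean_flow_ml_s: float
    caudal_mean_flow_ml_min: float
    cranial_mean_flow_ml_min: float
    sv_bradley_ul: float
    sv_bateman_ul: float
    net_volume_ul: float
    caudal_volume_ul: float
    cranial_volume_ul: float
    mean_flow_convention: str = "conditional"
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "area_mm2",
                "caudal_max_velocity_cm_s",
                "cranial_max_velocity_cm_s",
                "caudal_mean_flow_ml_s",
                "cranial_mean_flow_ml_s",
                "caudal_mean_flow_ml_min",
                "cranial_mean_flow_ml_min",
                "sv_bradley_ul",
                "sv_bateman_ul",
                "net_volume_ul",
                "caudal_volume_ul",
                "cranial_volume_ul",
            )
        }
        d["mean_flow_convention"] = self.mean_flow_convention
        d["flags"] = dict(self.flags)
        return d


def phase_to_velocity(series: PCMRISeries) -> VelocityField:
    """Decode phase into velocity: v = (phi / pi) * V_enc, cm/s.

    Emits an aliasing warning when more than 1% of voxel-frame samples sit
    within 2% of +/- V_enc — near-wrap values are indistinguishable from
    wrapped ones, mirroring the acquisition-time "check for aliasing"
    protocol.
    """
    v = (series.phase / np.pi) * series.venc_cm_s
    near = np.abs(np.abs(v) - series.venc_cm_s) <= 0.02 * series.venc_cm_s
    frac = float(near.mean())
    if frac > 0.01:
        warnings.warn(
            f"{frac:.1%} of voxel-frame samples within 2% of +/-V_enc; "
            "velocities may be aliased (wrapped)",
            RuntimeWarning,
            stacklevel=2,
        )
    return VelocityField(
        v=v,
        venc_cm_s=series.venc_cm_s,
        pixel_spacing_mm=series.pixel_spacing_mm,
        period_s=series.period_s,
        frame_times=np.asarray(series.frame_times, dtype=float),
        gating=series.gating,
    )


def eddy_correction(
    vel: VelocityField, static_mask, flow_roi=None
) -> VelocityField:
    """Remove the static-tissue background offset from the velocity field.

    The scalar mean velocity over (static region x all frames) — the
    eddy-current / accumulated-phase surrogate — is subtracted from every
    voxel and frame; the offset is recorded on the returned field.  A
    constant simulated offset is cancelled exactly, and reapplying the
    correction with the same static region is a no-op.
    """
    static = _mask_array(static_mask)
    if not static.any():
        raise ValueError("static region is empty")
    if flow_roi is not None:
        roi = _mask_array(flow_roi)
        if (static & roi).any():
            raise ValueError("static region overlaps the flow ROI")
    offset = float(vel.v[static, :].mean())
    return VelocityField(
        v=vel.v - offset,
        venc_cm_s=vel.venc_cm_s,
        pixel_spacing_mm=vel.pixel_spacing_mm,
        period_s=vel.period_s,
        frame_times=vel.frame_times,
        corrected=True,
        correction_offset_cm_s=vel.correction_offset_cm_s + offset,
        gating=vel.gating,
    )


def flow_waveform(vel: VelocityField, roi, pixel_area_mm2: float | None = None) -> FlowWaveform:
    """ROI-integrated volumetric flow per frame: q(t) = sum_roi v * area.

    Output in mL/s via the 1 cm/s * 1 mm^2 = 0.01 mL/s conversion.
    """
    mask = _mask_array(roi)
    if not mask.any():
        raise ValueError("empty ROI")
    if pixel_area_mm2 is None:
        pixel_area_mm2 = vel.pixel_area_mm2
    q = vel.v[mask, :].sum(axis=0) * pixel_area_mm2 * CM_S_MM2_TO_ML_S
    return FlowWaveform(q=q, times=vel.frame_times, period_s=vel.period_s)


def _close_cycle(q: np.ndarray, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Append the wrap-around node (frame 0 at t=1) for periodic integrals."""
    return np.append(q, q[0]), np.append(times, times[0] + 1.0)


def cycle_volumes_ul(q_ml_s: np.ndarray, times: np.ndarray, period_s: float) -> tuple[float, float]:
    """(caudal, cranial) lobe volumes in uL by periodic trapezoid rule.

    The caudal volume is |integral of min(q,0)|, cranial is the integral of
    max(q,0); both are non-negative magnitudes.
    """
    qc, tc = _close_cycle(np.asarray(q_ml_s, dtype=float), np.asarray(times, dtype=float))
    caudal = abs(np.trapezoid(np.minimum(qc, 0.0), tc)) * period_s * 1000.0
    cranial = np.trapezoid(np.maximum(qc, 0.0), tc) * period_s * 1000.0
    return float(caudal), float(cranial)


def hydrodynamic_metrics(
    flow: FlowWaveform,
    vel: VelocityField,
    roi,
    period_s: float | None = None,
    mean_flow_convention: str = "conditional",
) -> HydrodynamicMetrics:
    """Compute the full metric set for one series on one ROI.

    ``mean_flow_convention`` selects the directional mean-flow reading:

    * ``"conditional"`` (default): mean of |q(t)| over the frames where q
      has the given sign — the per-lobe characteristic flow, numerically
      SV / lobe duration.
    * ``"rectified"``: mean of the half-wave-rectified |q| over the whole
      cycle.

    A waveform that never changes sign yields zero for the absent
    direction's metrics and sets the ``one_sided`` flag rather than
    raising.
    """
    if mean_flow_convention not in ("conditional", "rectified"):
        raise ValueError(f"unknown mean_flow_convention {mean_flow_convention!r}")
    mask = _mask_array(roi)
    if not mask.any():
        raise ValueError("empty ROI")
    if period_s is None:
        period_s = flow.period_s
    q = np.asarray(flow.q, dtype=float)
    caudal_vol, cranial_vol = cycle_volumes_ul(q, flow.times, period_s)

    vroi = vel.v[mask, :]
    caudal_max = float(max(0.0, -vroi.min()))
    cranial_max = float(max(0.0, vroi.max()))

    flags: dict = {}
    neg, pos = q[q < 0], q[q > 0]
    if len(neg) == 0 or len(pos) == 0:
        flags["one_sided"] = True
    if mean_flow_convention == "conditional":
        caudal_mean = float(np.abs(neg).mean()) if len(neg) else 0.0
        cranial_mean = float(pos.mean()) if len(pos) else 0.0
    else:
        caudal_mean = float(np.abs(np.minimum(q, 0.0)).mean())
        cranial_mean = float(np.maximum(q, 0.0).mean())

    return HydrodynamicMetrics(
        area_mm2=float(mask.sum()) * vel.pixel_area_mm2,
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
        mean_flow_convention=mean_flow_convention,
        flags=flags,
    )


def stroke_volume_ratio(asv_ul: float, cistern_sv_ul: float) -> float:
    """Aqueductal-to-cisternal stroke volume ratio, in percent."""
    if not cistern_sv_ul > 0:
        raise ValueError("cistern stroke volume must be positive")
    return 100.0 * asv_ul / cistern_sv_ul
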