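"""Velocity decoding, eddy correction and the hydrodynamic metric set."""

import warnings

import numpy as np
import pytest

from csfpulse.hydrodynamics import (
    CM_S_MM2_TO_ML_S,
    FlowWaveform,
    VelocityField,
    cycle_volumes_ul,
    eddy_correction,
    flow_waveform,
    hydrodynamic_metrics,
    phase_to_velocity,
    stroke_volume_ratio,
)
from csfpulse.io import PCMRISeries
from tests.conftest import make_series


def _field(v, venc=10.0, spacing=1.0, period=1.0):
    v = np.asarray(v, dtype=float)
    return VelocityField(
        v=v,
        venc_cm_s=venc,
        pixel_spacing_mm=spacing,
        period_s=period,
        frame_times=np.arange(v.shape[2]) / v.shape[2],
    )


class TestPhaseToVelocity:
    def test_linear_encoding(self):
        phase = np.zeros((2, 2, 10))
        phase[0, 0, 0] = np.pi / 2
        s = PCMRISeries(np.ones((2, 2, 10)), phase, venc_cm_s=10.0,
                        pixel_spacing_mm=1.0, period_s=1.0)
        vel = phase_to_velocity(s)
        assert vel.v[0, 0, 0] == pytest.approx(5.0)
        assert vel.v[1, 1, 5] == 0.0

    def test_aliasing_warning_near_venc(self):
        phase = np.full((4, 4, 10), 0.999 * np.pi)
        s = PCMRISeries(np.ones((4, 4, 10)), phase, venc_cm_s=10.0,
                        pixel_spacing_mm=1.0, period_s=1.0)
        with pytest.warns(RuntimeWarning, match="alias"):
            phase_to_velocity(s)


class TestEddyCorrection:
    def test_constant_offset_cancelled_exactly(self):
        series, truth = make_series("aqueduct", clean=True,
                                    static_phase_offset_rad=0.3)
        ref, _ = make_series("aqueduct", clean=True)
        static = ~truth.mask.mask
        vel = eddy_correction(phase_to_velocity(series), static, flow_roi=truth.mask)
        vel_ref = phase_to_velocity(ref)
        assert np.abs(vel.v - vel_ref.v).max() < 1e-12
        expected = (0.3 / np.pi) * series.venc_cm_s
        assert vel.correction_offset_cm_s == pytest.approx(expected, rel=1e-9)

    def test_zero_offset_recorded_zero(self, aqueduct_clean):
        series, truth = aqueduct_clean
        vel = phase_to_velocity(series)
        out = eddy_correction(vel, ~truth.mask.mask)
        assert out.correction_offset_cm_s == 0.0
        assert np.array_equal(out.v, vel.v)

    def test_idempotent(self, aqueduct_noisy):
        series, truth = aqueduct_noisy
        static = ~truth.mask.mask
        v1 = eddy_correction(phase_to_velocity(series), static)
        v2 = eddy_correction(v1, static)
        assert np.abs(v2.v - v1.v).max() < 1e-12

    def test_noisy_offset_recovery_across_seeds(self):
        """Estimated offset tracks the closed-form (0.3/pi)*V_enc within
        the empirical standard error over 20 seeds."""
        offsets = []
        for seed in range(20):
            series, truth = make_series("aqueduct", seed=seed,
                                        static_phase_offset_rad=0.3)
            static = ~truth.mask.mask & (series.magnitude.mean(axis=2) < 100)
            vel = eddy_correction(phase_to_velocity(series), static, flow_roi=truth.mask)
            offsets.append(vel.correction_offset_cm_s)
        offsets = np.array(offsets)
        expected = (0.3 / np.pi) * series.venc_cm_s
        se = offsets.std(ddof=1) / np.sqrt(len(offsets))
        assert abs(offsets.mean() - expected) <= 2 * se + 1e-12

    def test_overlap_with_roi_rejected(self, aqueduct_clean):
        series, truth = aqueduct_clean
        vel = phase_to_velocity(series)
        with pytest.raises(ValueError, match="overlap"):
            eddy_correction(vel, truth.mask.mask, flow_roi=truth.mask)

    def test_empty_static_region_rejected(self, aqueduct_clean):
        series, _ = aqueduct_clean
        with pytest.raises(ValueError, match="empty"):
            eddy_correction(phase_to_velocity(series),
                            np.zeros(series.shape[:2], dtype=bool))


class TestFlowWaveform:
    def test_unit_conversion_single_voxel(self):
        v = np.zeros((1, 1, 10))
        v[0, 0, :] = 1.0  # 1 cm/s steady
        mask = np.ones((1, 1), dtype=bool)
        q = flow_waveform(_field(v), mask, pixel_area_mm2=1.0)
        assert np.allclose(q.q, 0.01)  # 0.01 mL/s = 0.6 mL/min

    def test_linearity_in_roi_size(self):
        v = np.ones((2, 2, 10)) * 2.0
        one = np.zeros((2, 2), dtype=bool)
        one[0, 0] = True
        q1 = flow_waveform(_field(v), one, 1.0)
        q4 = flow_waveform(_field(v), np.ones((2, 2), dtype=bool), 1.0)
        assert np.allclose(q4.q, 4 * q1.q)

    def test_pixel_area_scaling(self):
        v = np.ones((2, 2, 10))
        mask = np.ones((2, 2), dtype=bool)
        q1 = flow_waveform(_field(v), mask, 1.0)
        q3 = flow_waveform(_field(v), mask, 3.0)
        assert np.allclose(q3.q, 3 * q1.q)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            flow_waveform(_field(np.ones((2, 2, 10))), np.zeros((2, 2), dtype=bool))


class TestMetrics:
    def _sine_flow(self, n=1000, amp=0.01, period=1.0):
        t = np.arange(n) / n
        return FlowWaveform(q=amp * np.sin(2 * np.pi * t), times=t, period_s=period)

    def test_sine_closed_form(self):
        """Symmetric 0.01 mL/s sine at 1 s period: each lobe integrates to
        0.01/pi mL ~ 3.183 uL; Bradley and Bateman SV coincide."""
        flow = self._sine_flow()
        v = np.zeros((1, 1, 1000))
        v[0, 0, :] = flow.q * 100.0  # single 1 mm^2 voxel
        m = hydrodynamic_metrics(flow, _field(v), np.ones((1, 1), dtype=bool))
        expect = 0.01 / np.pi * 1000.0
        assert m.caudal_volume_ul == pytest.approx(expect, rel=1e-4)
        assert m.cranial_volume_ul == pytest.approx(expect, rel=1e-4)
        assert m.sv_bradley_ul == pytest.approx(m.sv_bateman_ul, rel=1e-4)
        assert m.net_volume_ul == pytest.approx(0.0, abs=1e-6)

    def test_sv_recovery_at_30_frames(self):
        """Bradley SV from the noisy-free 30-frame pipeline lands within 2%
        of the designed 124.5 uL."""
        series, truth = make_series("aqueduct", clean=True)
        vel = phase_to_velocity(series)
        q = flow_waveform(vel, truth.mask)
        m = hydrodynamic_metrics(q, vel, truth.mask)
        assert m.sv_bradley_ul == pytest.approx(124.5, rel=0.02)
        assert m.sv_bradley_ul == pytest.approx(truth.true_metrics.sv_bradley_ul, rel=0.02)

    def test_trapezoid_vs_dense_quadrature(self):
        """30-frame periodic trapezoid volumes agree with 1000-point dense
        quadrature of the same continuous waveform within 2%."""
        from csfpulse.synthetic import WaveformParams, generate_flow_waveform

        wp = WaveformParams(period_s=0.87)
        coarse = generate_flow_waveform(wp, 30)
        dense = generate_flow_waveform(wp, 1000)
        c30 = cycle_volumes_ul(coarse.q, coarse.times, wp.period_s)
        c1000 = cycle_volumes_ul(dense.q, dense.times, wp.period_s)
        for a, b in zip(c30, c1000):
            assert a == pytest.approx(b, rel=0.02)

    def test_sign_flip_swaps_directions(self):
        series, truth = make_series("aqueduct", clean=True)
        vel = phase_to_velocity(series)
        q = flow_waveform(vel, truth.mask)
        m = hydrodynamic_metrics(q, vel, truth.mask)
        neg = _field(-vel.v, venc=vel.venc_cm_s, spacing=vel.pixel_spacing_mm,
                     period=vel.period_s)
        qn = flow_waveform(neg, truth.mask)
        mn = hydrodynamic_metrics(qn, neg, truth.mask)
        assert mn.caudal_volume_ul == pytest.approx(m.cranial_volume_ul, rel=1e-12)
        assert mn.cranial_max_velocity_cm_s == pytest.approx(m.caudal_max_velocity_cm_s)
        assert mn.caudal_mean_flow_ml_s == pytest.approx(m.cranial_mean_flow_ml_s)

    def test_bradley_close_to_bateman_for_zero_net(self):
        series, truth = make_series("aqueduct", clean=True)
        vel = phase_to_velocity(series)
        q = flow_waveform(vel, truth.mask)
        m = hydrodynamic_metrics(q, vel, truth.mask)
        assert abs(m.sv_bradley_ul - m.sv_bateman_ul) / m.sv_bradley_ul <= 0.05

    def test_one_sided_waveform_flagged(self):
        t = np.arange(30) / 30
        flow = FlowWaveform(q=np.abs(np.sin(2 * np.pi * t)) * 0.01, times=t, period_s=1.0)
        v = np.zeros((1, 1, 30))
        v[0, 0, :] = flow.q * 100
        m = hydrodynamic_metrics(flow, _field(v), np.ones((1, 1), dtype=bool))
        assert m.caudal_volume_ul == 0.0
        assert m.caudal_mean_flow_ml_s == 0.0
        assert m.flags.get("one_sided") is True

    def test_mean_flow_conventions(self):
        flow = self._sine_flow(n=1000, amp=1.0)
        v = np.zeros((1, 1, 1000))
        v[0, 0, :] = flow.q * 100
        mask = np.ones((1, 1), dtype=bool)
        cond = hydrodynamic_metrics(flow, _field(v), mask, mean_flow_convention="conditional")
        rect = hydrodynamic_metrics(flow, _field(v), mask, mean_flow_convention="rectified")
        # conditional mean of |sin| over its negative half = 2/pi; rectified
        # over the whole cycle halves it (tolerance covers the 1000-sample
        # discretization of the open half-cycle)
        assert cond.caudal_mean_flow_ml_s == pytest.approx(2 / np.pi, rel=5e-3)
        assert rect.caudal_mean_flow_ml_s == pytest.approx(1 / np.pi, rel=5e-3)
        assert cond.caudal_mean_flow_ml_min == pytest.approx(60 * 2 / np.pi, rel=5e-3)


class TestStrokeVolumeRatio:
    def test_basic_and_zero(self):
        assert stroke_volume_ratio(50.0, 100.0) == pytest.approx(50.0)
        assert stroke_volume_ratio(0.0, 100.0) == 0.0
        with pytest.raises(ValueError):
            stroke_volume_ratio(50.0, 0.0)

    def test_matched_cohort_recovery(self):
        """Estimated mean aqueduct/cistern SV ratio over 20 matched synthetic
        subjects designed at 50% lands within 2 SEM of 50%."""
        ratios = []
        for seed in range(20):
            sa, ta = make_series("aqueduct", seed=seed, caudal_volume_ul=150.0,
                                 cranial_volume_ul=150.0)
            sc, tc = make_series("cistern", seed=seed, caudal_volume_ul=300.0,
                                 cranial_volume_ul=300.0)
            vals = {}
            for s, t, key in ((sa, ta, "a"), (sc, tc, "c")):
                static = ~t.mask.mask & (s.magnitude.mean(axis=2) < 100)
                if t.artery_mask is not None:
                    static &= ~t.artery_mask
                vel = eddy_correction(phase_to_velocity(s), static, flow_roi=t.mask)
                q = flow_waveform(vel, t.mask)
                vals[key] = hydrodynamic_metrics(q, vel, t.mask).sv_bradley_ul
            ratios.append(stroke_volume_ratio(vals["a"], vals["c"]))
        ratios = np.array(ratios)
        sem = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 50.0) <= max(2 * sem, 0.5)
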