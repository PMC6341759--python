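"""Generator contracts: waveform shape/integrals, encoding round trips,
artery handling, determinism and cohort draws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfpulse.hydrodynamics import cycle_volumes_ul, phase_to_velocity
from csfpulse.synthetic import (
    ArteryParams,
    CohortSpec,
    GroupSpec,
    SceneParams,
    WaveformParams,
    build_waveform_model,
    generate_cohort,
    generate_flow_waveform,
    generate_pc_series,
    preset,
    simulate,
)
from tests.conftest import make_series


class TestFlowWaveform:
    def test_net_volume_matches_design(self):
        """Trapezoid net volume over the closed cycle equals the designed
        cranial-minus-caudal volume."""
        for caudal, cranial in [(124.5, 124.5), (100.0, 80.0), (0.0, 50.0)]:
            wp = WaveformParams(period_s=0.9, caudal_volume_ul=caudal, cranial_volume_ul=cranial)
            wf = generate_flow_waveform(wp, 30)
            assert wf.net_volume_ul() == pytest.approx(cranial - caudal, abs=1e-5)

    @pytest.mark.parametrize("latency", [0.0, 0.2, 0.327, 0.5, 0.8])
    def test_minimum_at_requested_latency(self, latency):
        """The continuous waveform minimum sits at the requested latency
        within half a frame; the sampled argmin within one frame."""
        wp = WaveformParams(period_s=0.87, peak_caudal_latency=latency)
        model = build_waveform_model(wp)
        tmin = model.argmin()
        err = min(abs(tmin - latency), 1 - abs(tmin - latency))  # circular
        assert err <= 0.5 / 30
        wf = generate_flow_waveform(wp, 30)
        frame = np.argmin(wf.q)
        expect = latency * 30
        circ = min(abs(frame - expect), 30 - abs(frame - expect))
        assert circ <= 1.0

    def test_zero_amplitude_is_all_zero(self):
        wp = WaveformParams(period_s=1.0, caudal_volume_ul=0.0, cranial_volume_ul=0.0)
        wf = generate_flow_waveform(wp, 30)
        assert np.allclose(wf.q, 0.0, atol=1e-12)

    def test_caudal_lobe_integral_dense_quadrature(self):
        """Dense (1000-frame) trapezoid quadrature of the negative lobe
        recovers the designed caudal volume within 0.5%."""
        wp = WaveformParams(
            period_s=1.0,
            peak_caudal_latency=0.25,
            caudal_volume_ul=100.0,
            cranial_volume_ul=100.0,
            caudal_fraction=0.5,
        )
        wf = generate_flow_waveform(wp, 1000)
        caudal, cranial = cycle_volumes_ul(wf.q, wf.times, wp.period_s)
        assert caudal == pytest.approx(100.0, rel=0.005)
        assert cranial == pytest.approx(100.0, rel=0.005)

    def test_biphasic(self, aqueduct_waveform):
        _, wf = aqueduct_waveform
        assert wf.q.min() < 0 < wf.q.max()

    @pytest.mark.parametrize("bad", [
        dict(peak_caudal_latency=1.0),
        dict(peak_caudal_latency=-0.1),
        dict(caudal_fraction=0.0),
        dict(caudal_fraction=1.0),
        dict(period_s=0.0),
        dict(caudal_volume_ul=-1.0),
    ])
    def test_invalid_params_rejected(self, bad):
        kw = dict(period_s=1.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            WaveformParams(**kw)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        latency=st.floats(0.05, 0.95),
        frac=st.floats(0.25, 0.75),
        caudal=st.floats(20.0, 400.0),
        cranial=st.floats(20.0, 400.0),
    )
    def test_net_volume_property(self, latency, frac, caudal, cranial):
        """Net-flow conservation holds over the whole parameter family."""
        wp = WaveformParams(
            period_s=0.9,
            peak_caudal_latency=latency,
            caudal_volume_ul=caudal,
            cranial_volume_ul=cranial,
            caudal_fraction=frac,
        )
        wf = generate_flow_waveform(wp, 30)
        assert wf.net_volume_ul() == pytest.approx(cranial - caudal, abs=1e-4)
        model = build_waveform_model(wp)
        tmin = model.argmin()
        err = min(abs(tmin - latency), 1 - abs(tmin - latency))
        assert err <= 0.5 / 30


class TestPCSeries:
    def test_velocity_round_trip_noise_free(self):
        """Decoding phase recovers the per-voxel velocity field exactly
        when nothing wraps (plug profile, no offset, no noise)."""
        series, truth = make_series("aqueduct", clean=True, velocity_profile="plug")
        vel = phase_to_velocity(series)
        m = truth.mask.mask
        wp = truth.waveform_params
        wf = generate_flow_waveform(wp, 30)
        # plug: every ROI voxel carries flow / (n*area)
        expected = wf.q * 100.0 / (m.sum() * series.pixel_area_mm2)
        assert np.abs(vel.v[m, :] - expected[None, :]).max() < 1e-9
        assert np.abs(vel.v[~m, :]).max() < 1e-12

    @pytest.mark.parametrize("profile", ["plug", "parabolic"])
    def test_roi_flow_matches_input_waveform(self, profile):
        series, truth = make_series("aqueduct", clean=True, velocity_profile=profile)
        from csfpulse.hydrodynamics import flow_waveform

        vel = phase_to_velocity(series)
        q = flow_waveform(vel, truth.mask)
        wf = generate_flow_waveform(truth.waveform_params, 30)
        scale = np.abs(wf.q).max()
        assert np.abs(q.q - wf.q).max() / scale < 1e-9

    def test_zero_waveform_zero_phase(self):
        series, _ = make_series(
            "aqueduct", clean=True, caudal_volume_ul=0.0, cranial_volume_ul=0.0
        )
        assert np.abs(series.phase).max() < 1e-12

    def test_determinism(self):
        a, _ = make_series("cistern", seed=11)
        b, _ = make_series("cistern", seed=11)
        assert np.array_equal(a.phase, b.phase)
        assert np.array_equal(a.magnitude, b.magnitude)

    def test_artery_disjoint_and_excluded_from_truth(self, cistern_noisy):
        series, truth = cistern_noisy
        assert truth.artery_mask is not None and truth.artery_mask.any()
        assert not (truth.artery_mask & truth.mask.mask).any()
        assert truth.wrap_occurred  # default artery exceeds V_enc

    def test_double_wrap_rejected(self):
        """ROI velocities beyond 2*V_enc make ground truth ambiguous."""
        with pytest.raises(ValueError, match="2\\*V_enc"):
            make_series("aqueduct", clean=True, venc_cm_s=2.0)

    def test_flow_voids_attenuate_magnitude_only(self):
        s_void, t_void = make_series("aqueduct", clean=True, flow_void_fraction=0.5)
        s_ref, _ = make_series("aqueduct", clean=True)
        assert t_void.void_mask is not None and t_void.void_mask.any()
        assert np.array_equal(s_void.phase, s_ref.phase)  # phase preserved
        assert (s_void.magnitude[t_void.void_mask, :] < s_ref.magnitude[t_void.void_mask, :]).all()

    def test_true_metrics_match_recomputation_from_dense_field(self):
        """Analytic ground-truth metrics agree with metrics recomputed from
        a densely-sampled noise-free velocity field to 1e-6 relative."""
        from csfpulse.hydrodynamics import flow_waveform, hydrodynamic_metrics

        scene, wp = preset("aqueduct", noise_sd_phase_rad=0.0, noise_sd_magnitude=0.0,
                           static_phase_offset_rad=0.0)
        wf = generate_flow_waveform(wp, 4096)
        series, truth = generate_pc_series(scene, wf)
        vel = phase_to_velocity(series)
        q = flow_waveform(vel, truth.mask)
        m = hydrodynamic_metrics(q, vel, truth.mask)
        t = truth.true_metrics
        assert m.sv_bradley_ul == pytest.approx(t.sv_bradley_ul, rel=1e-6)
        assert m.caudal_volume_ul == pytest.approx(t.caudal_volume_ul, rel=1e-6)
        assert m.caudal_max_velocity_cm_s == pytest.approx(t.caudal_max_velocity_cm_s, rel=1e-4)
        assert m.area_mm2 == pytest.approx(t.area_mm2)

    def test_scene_validation(self):
        with pytest.raises(ValueError, match="4 voxels"):
            SceneParams(roi_area_mm2=1.0, pixel_spacing_mm=1.0)
        with pytest.raises(ValueError):
            SceneParams(venc_cm_s=0.0)
        with pytest.raises(ValueError):
            SceneParams(noise_sd_phase_rad=-0.1)

    def test_artery_overlapping_roi_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_series("cistern", clean=True,
                        artery=ArteryParams(center=(24, 22), area_mm2=12.0))


class TestCohort:
    def _spec(self, seed=0):
        return CohortSpec(
            groups=(
                GroupSpec(name="pre", group="pre_shunt", n=4, site="aqueduct",
                          distributions={"latency": ("normal", 0.245, 0.063)}),
                GroupSpec(name="ctl", group="control", n=2, site="aqueduct",
                          distributions={"latency": ("normal", 0.296, 0.132)}),
            ),
            seed=seed,
        )

    def test_sizes_and_truth_recorded(self):
        subjects, log = generate_cohort(self._spec())
        assert len(subjects) == 6
        assert len(log) == 6
        assert {g for g, _, _ in subjects} == {"pre", "ctl"}
        for _, _, truth in subjects:
            assert 0.0 <= truth.true_pfl < 1.0

    def test_determinism_bit_identical(self):
        sa, la = generate_cohort(self._spec(seed=3))
        sb, lb = generate_cohort(self._spec(seed=3))
        for (_, s1, _), (_, s2, _) in zip(sa, sb):
            assert np.array_equal(s1.phase, s2.phase)
        assert la.equals(lb)

    def test_degenerate_distribution_identical_truths(self):
        spec = CohortSpec(
            groups=(GroupSpec(name="g", group="control", n=3, site="aqueduct",
                              distributions={"latency": ("normal", 0.30, 0.0)}),),
            seed=1,
        )
        subjects, _ = generate_cohort(spec)
        pfls = {t.true_pfl for _, _, t in subjects}
        assert pfls == {0.30}
        # different noise realizations per subject
        assert not np.array_equal(subjects[0][1].phase, subjects[1][1].phase)

    def test_truncation_recorded_in_draw_log(self):
        spec = CohortSpec(
            groups=(GroupSpec(name="g", group="control", n=6, site="aqueduct",
                              distributions={"sv_ul": ("normal", 5.0, 30.0)}),),
            seed=2,
        )
        _, log = generate_cohort(spec)
        assert log["sv_ul_truncated"].any()
        assert (log["sv_ul"] >= 1.0).all()
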