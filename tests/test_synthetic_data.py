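import numpy as np
import pytest

from neuritemito.imaging_io import StimulationProtocol
from neuritemito.synthetic_data import (
    GenerationError,
    MitoCalciumSpec,
    OpticsModel,
    ParticleSpec,
    PlacementError,
    SamplingError,
    calcium_kernel,
    expected_frame,
    gen_calcium_recording,
    gen_frap_experiment,
    gen_proximity_scene,
    gen_rogfp_scene,
    gen_transport_stream,
    kernel_area,
    kernel_peak_time,
    place_axial_objects,
    render_frame,
    substream,
    symmetric_z_count,
)


class TestRenderFrame:
    def test_dark_frame(self):
        opt = OpticsModel(read_noise_e=0.0, offset_counts=80.0)
        img = render_frame(np.zeros((16, 16)), opt, seed=0)
        assert np.all(img == 80.0)

    def test_determinism(self, optics):
        field = np.full((20, 20), 30.0)
        a = render_frame(field, optics, seed=42)
        b = render_frame(field, optics, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_shot_noise_scaling(self):
        # relative SD shrinks as 1/sqrt(photons) toward the bright limit
        rel_sds = []
        for ppu in (1.0, 100.0):
            opt = OpticsModel(photons_per_unit=ppu, read_noise_e=0.0,
                              offset_counts=0.0, gain_counts_per_photon=1.0)
            img = render_frame(np.full((200, 200), 50.0), opt, seed=1)
            rel_sds.append(img.std() / img.mean())
        assert rel_sds[1] < rel_sds[0] / 5  # sqrt(100) = 10x fewer, with slack
        # and the absolute level matches sqrt(N)/N
        expected = 1.0 / np.sqrt(50.0 * 100.0)
        assert rel_sds[1] == pytest.approx(expected, rel=0.05)

    def test_noise_variance_matches_camera_model(self):
        opt = OpticsModel(read_noise_e=2.0, offset_counts=100.0,
                          gain_counts_per_photon=2.0)
        img = render_frame(np.full((400, 400), 50.0), opt, seed=3)
        expected = opt.gain_counts_per_photon**2 * 50.0 + \
            (opt.read_noise_e * opt.gain_counts_per_photon) ** 2
        assert img.size >= 1e5
        assert img.var() == pytest.approx(expected, rel=0.05)

    def test_expected_frame_is_noiseless_limit(self, optics):
        field = np.zeros((24, 24))
        field[12, 12] = 100.0
        exp = expected_frame(field, optics)
        assert np.all(exp >= optics.offset_counts)
        np.testing.assert_allclose(
            render_frame(field, optics, seed=0, noise=False), exp)


class TestSymmetricZ:
    def test_pm_2p5_um_at_0p25(self):
        assert symmetric_z_count(2.5, 0.25) == 21

    def test_zero_range(self):
        assert symmetric_z_count(0.0, 0.25) == 1


class TestCalciumGenerator:
    def test_flat_trace_without_events(self, protocol_30s):
        spec = MitoCalciumSpec(amplitudes=[0.0] * 5)
        traces, truth = gen_calcium_recording(protocol_30s, [spec],
                                              noise_sd=0.0, dt_s=0.1, seed=0)
        np.testing.assert_allclose(traces[0].f_corr, spec.baseline)
        assert truth.records == []

    def test_five_stimulus_windows_in_150s(self, protocol_30s):
        spec = MitoCalciumSpec(amplitudes=[1.0, 0.5, 0.4, 0.3, 0.2])
        _, truth = gen_calcium_recording(protocol_30s, [spec], dt_s=0.1, seed=0)
        assert len(truth.records) == 5
        assert [r["onset_s"] for r in truth.records] == [0, 30, 60, 90, 120]

    def test_noiseless_peak_equals_amplitude(self):
        # closed-form kernel maximum: sampled peak equals a when the peak
        # time lands exactly on the sampling grid
        dt = 0.1
        tp = kernel_peak_time(0.2, 3.0)
        onset = round((10.0 + tp) / dt) * dt - tp
        prot = StimulationProtocol(pulse_duration_s=1.0, onset_times_s=[onset])
        spec = MitoCalciumSpec(amplitudes=[1.7])
        traces, _ = gen_calcium_recording(prot, [spec], noise_sd=0.0,
                                          duration_s=60.0, dt_s=dt, seed=0)
        dff_true = traces[0].f_corr / spec.baseline - 1.0
        assert np.max(dff_true) == pytest.approx(1.7, abs=1e-9)

    def test_kernel_area_closed_form(self):
        t = np.arange(0, 400, 0.001)
        numeric = np.trapezoid(calcium_kernel(t), dx=0.001)
        assert numeric == pytest.approx(kernel_area(), rel=1e-5)

    def test_undersampling_rejected(self, protocol_30s):
        spec = MitoCalciumSpec(amplitudes=[1.0] * 5)
        with pytest.raises(SamplingError):
            gen_calcium_recording(protocol_30s, [spec], dt_s=0.25, seed=0)

    def test_response_class_validation(self):
        with pytest.raises(GenerationError):
            MitoCalciumSpec(amplitudes=[1.0, 2.0], response_class="first-dominant")
        with pytest.raises(GenerationError):
            MitoCalciumSpec(amplitudes=[2.0, 1.0], response_class="late-dominant")

    def test_determinism_and_substream_stability(self, protocol_30s):
        specs = [MitoCalciumSpec(amplitudes=[1.0, 0.5, 0.4, 0.3, 0.2]),
                 MitoCalciumSpec(amplitudes=[0.5, 1.0, 0.4, 0.3, 0.2],
                                 response_class="late-dominant")]
        t1, _ = gen_calcium_recording(protocol_30s, specs, noise_sd=0.1,
                                      dt_s=0.1, seed=5)
        t2, _ = gen_calcium_recording(protocol_30s, specs, noise_sd=0.1,
                                      dt_s=0.1, seed=5)
        np.testing.assert_array_equal(t1[0].f_raw, t2[0].f_raw)
        # dropping the second mito must not change the first one's noise
        t3, _ = gen_calcium_recording(protocol_30s, specs[:1], noise_sd=0.1,
                                      dt_s=0.1, seed=5)
        np.testing.assert_array_equal(t1[0].f_raw, t3[0].f_raw)


class TestRogfpGenerator:
    def test_truth_ratios_follow_model(self):
        _, _, _, truth = gen_rogfp_scene(n_mito=40, seed=0, noise=False,
                                         ratio_model={"means": [0.03],
                                                      "sds": [0.005]})
        ratios = np.array([r["ratio_true"] for r in truth.records])
        assert abs(ratios.mean() - 0.03) < 0.004
        assert len(ratios) == 40

    def test_bimodal_model_components(self):
        model = {"means": [0.05, 0.09], "sds": [0.01, 0.01], "weights": [0.5, 0.5]}
        _, _, _, truth = gen_rogfp_scene(n_mito=60, ratio_model=model, seed=1)
        comps = {r["component"] for r in truth.records}
        assert comps == {0, 1}

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(GenerationError):
            gen_rogfp_scene(n_mito=3, mito_sigma_um=(0.0, 0.2), seed=0)

    def test_determinism(self):
        a = gen_rogfp_scene(n_mito=4, seed=9)[1]
        b = gen_rogfp_scene(n_mito=4, seed=9)[1]
        np.testing.assert_array_equal(a.pages, b.pages)


class TestFrapGenerator:
    def test_default_schedule_has_10_timepoints(self):
        stacks, _, _, truth = gen_frap_experiment(seed=0, noise=False)
        assert len(stacks) == 10
        assert [r["t_min"] for r in truth.records] == \
            [0.0, 0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0]
        assert truth.records[0]["is_pre"]

    def test_default_z_geometry_21_planes(self):
        stacks, _, _, _ = gen_frap_experiment(seed=0, noise=False)
        assert all(s.n_pages == 21 for s in stacks)
        assert stacks[0].axial_span_um == pytest.approx(5.0)

    def test_saturated_recovery(self):
        _, _, _, truth = gen_frap_experiment(k_per_min=1e6, plateau_pct=60.0,
                                             seed=0, noise=False)
        post = [r for r in truth.records if not r["is_pre"] and r["t_min"] > 0]
        f_pre, f0 = truth.params["f_pre"], truth.params["f0"]
        plateau_level = f0 + (f_pre - f0) * 0.6
        assert all(r["level"] == pytest.approx(plateau_level) for r in post)

    def test_immobile_pool(self):
        _, _, _, truth = gen_frap_experiment(plateau_pct=0.0, seed=0, noise=False)
        post = [r for r in truth.records if not r["is_pre"]]
        assert all(r["level"] == pytest.approx(truth.params["f0"]) for r in post)

    def test_invalid_parameters(self):
        with pytest.raises(GenerationError):
            gen_frap_experiment(plateau_pct=120.0)
        with pytest.raises(GenerationError):
            gen_frap_experiment(k_per_min=-1.0)


class TestTransportGenerator:
    def test_empty_scene_is_background(self, optics):
        stream, _, truth = gen_transport_stream([], duration_s=2.0, dt_s=0.2,
                                                seed=0, noise=False)
        assert np.ptp(stream.pages) < 1e-9 + optics.offset_counts
        assert truth.records == []

    def test_kinematics_closed_form(self):
        p = ParticleSpec(v_um_s=2.0, direction=1, start_pos_um=0.0)
        t = np.array([0.0, 10.0, 50.0])
        np.testing.assert_allclose(p.position_um(t), [0.0, 20.0, 100.0])

    def test_pause_freezes_motion(self):
        p = ParticleSpec(v_um_s=2.0, direction=1, start_pos_um=0.0,
                         pauses=[(3.0, 6.0)])
        np.testing.assert_allclose(p.position_um(np.array([3.0, 6.0, 7.0])),
                                   [6.0, 6.0, 8.0])

    def test_frame_count(self):
        stream, _, _ = gen_transport_stream(
            [ParticleSpec(v_um_s=0.0, motile=False, start_pos_um=10.0)],
            duration_s=50.0, dt_s=0.1, seed=0, noise=False)
        assert stream.n_pages == 500

    def test_stationary_particle_never_moves(self):
        p = ParticleSpec(v_um_s=3.0, motile=False, start_pos_um=12.0)
        assert np.all(p.position_um(np.linspace(0, 50, 100)) == 12.0)


class TestProximityGenerator:
    def test_target_zero_all_far(self):
        _, _, rows = place_axial_objects(10, 3, 0.0, 120.0, seed=0)
        assert all(r["nearest_gap_um"] >= 1.5 for r in rows)

    def test_target_one_all_close(self):
        _, _, rows = place_axial_objects(10, 10, 1.0, 120.0, seed=0)
        assert sum(r["proximal"] for r in rows) == 10
        assert all(r["nearest_gap_um"] < 1.0 for r in rows)

    def test_target_61_percent_of_100(self):
        _, _, rows = place_axial_objects(100, 61, 0.61, 800.0, seed=0)
        assert sum(r["proximal"] for r in rows) == 61

    def test_infeasible_density(self):
        with pytest.raises(PlacementError):
            place_axial_objects(50, 50, 1.0, 20.0, seed=0)

    def test_render_determinism(self):
        a = gen_proximity_scene(n_mito=5, seed=3)[0]
        b = gen_proximity_scene(n_mito=5, seed=3)[0]
        np.testing.assert_array_equal(a.pages, b.pages)


def test_substream_independence():
    a = substream(1, 2, 3).normal(size=5)
    b = substream(1, 2, 3).normal(size=5)
    c = substream(1, 2, 4).normal(size=5)
    np.testing.assert_array_equal(a, b)
    assert not np.allclose(a, c)
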