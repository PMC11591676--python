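"""Simulator physics: saturation curve, first-order kinetics, noise
decomposition, drift, rendering, and the extraction round trip."""

import numpy as np
import pytest

from co2lens import (
    GasProtocol,
    Phase,
    SensorModelParams,
    SpotLayout,
    compute_absorbance,
    extract_traces,
    detect_spots,
    render_frames,
    simulate_absorbance_traces,
    steady_state_response,
)
from co2lens.synthetic import count_decay_events, count_rise_events

from conftest import make_traces


class TestSteadyState:
    @pytest.mark.parametrize(
        "conc, expected",
        [
            (0.0, 0.0),
            (5000.0, 0.10673 / 2),  # half-saturation identity
            (1000.0, 0.0177883),  # 0.10673 * 1000 / 6000
        ],
    )
    def test_anchor_values(self, default_params, conc, expected):
        assert steady_state_response(conc, default_params) == pytest.approx(expected, rel=1e-4)

    def test_negative_concentration_rejected(self, default_params):
        with pytest.raises(ValueError, match="concentration"):
            steady_state_response(-1.0, default_params)

    def test_monotone_and_saturating(self, default_params):
        c = np.logspace(0, 6, 40)
        y = np.array([steady_state_response(x, default_params) for x in c])
        assert np.all(np.diff(y) > 0)
        assert y[-1] < default_params.effective_dA_max

    def test_channel_weights_and_mof(self, default_params):
        r = steady_state_response(1000, default_params, "R")
        g = steady_state_response(1000, default_params, "G")
        b = steady_state_response(1000, default_params, "B")
        assert r > g > b > 0
        off = default_params.replace(mof_enabled=False)
        assert steady_state_response(1000, off) == pytest.approx(r / default_params.mof_factor)

    def test_interferents_inert_by_default(self, default_params):
        assert steady_state_response(20000, default_params, gas_id="o2") == 0.0


class TestProtocol:
    def test_overlapping_phases_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GasProtocol(phases=(Phase("air", 0, 0, 100), Phase("co2", 500, 50, 100)))

    def test_air_with_concentration_rejected(self):
        with pytest.raises(ValueError, match="air"):
            GasProtocol(phases=(Phase("air", 100.0, 0, 100),))

    def test_bad_frame_interval_rejected(self):
        with pytest.raises(ValueError, match="frame_interval"):
            GasProtocol(phases=(Phase("air", 0, 0, 100),), frame_interval=0.0)

    def test_alternating_structure(self, six_cycle_protocol):
        assert len(six_cycle_protocol.exposure_phases()) == 6
        assert len(six_cycle_protocol.purge_windows()) == 7
        assert six_cycle_protocol.total_duration == 13 * 120.0


class TestKinetics:
    def test_first_order_t90_closed_form(self, uniform_params):
        proto = GasProtocol.alternating([1000.0], 10.0, 400.0, tail_purge=False)
        sim = simulate_absorbance_traces(proto, uniform_params)
        a = sim.true[0, 0, :]
        da_ss = steady_state_response(1000.0, uniform_params)
        t90 = uniform_params.tau_response * np.log(10.0)
        onset = 10.0
        level = np.interp(onset + t90, sim.time, a)
        assert level == pytest.approx(0.9 * da_ss, rel=1e-3)
        assert a[-1] == pytest.approx(da_ss, rel=1e-4)

    def test_six_cycles_give_six_rises_and_decays(self, noiseless_params, six_cycle_protocol):
        sim = simulate_absorbance_traces(six_cycle_protocol, noiseless_params)
        for s in range(6):
            assert count_rise_events(sim.true[s, 0, :]) == 6
            assert count_decay_events(sim.true[s, 0, :]) == 6

    def test_spot_amplitudes_scale_truth(self, noiseless_params):
        proto = GasProtocol.alternating([1000.0], 10.0, 300.0, tail_purge=False)
        sim = simulate_absorbance_traces(proto, noiseless_params)
        plateaus = sim.true[:, 0, -1]
        expected = np.array(noiseless_params.spot_amplitudes) * steady_state_response(
            1000.0, noiseless_params
        )
        np.testing.assert_allclose(plateaus, expected, rtol=1e-3)


class TestNoiseModel:
    def test_single_spot_baseline_sd(self, baseline_protocol):
        # sqrt(sigma_shared^2 + sigma_indep^2) = 3.171e-4
        sds = []
        for seed in range(1, 6):
            p = SensorModelParams(seed=seed, drift_amplitude=0.0)
            sim = simulate_absorbance_traces(baseline_protocol, p)
            sds.append(sim.noisy[0, 0, :].std(ddof=1))
        assert np.median(sds) == pytest.approx(3.171e-4, rel=0.15)

    def test_averaging_law_independent_noise(self, baseline_protocol):
        # with no shared component the 6-spot mean has sd sigma_indep/sqrt(6)
        sds = []
        for seed in range(1, 11):
            p = SensorModelParams(seed=seed, sigma_shared=0.0, drift_amplitude=0.0)
            sim = simulate_absorbance_traces(baseline_protocol, p)
            sds.append(sim.noisy[:, 0, :].mean(axis=0).std(ddof=1))
        expected = 2.82e-4 / np.sqrt(6)
        assert np.mean(sds) == pytest.approx(expected, rel=0.2)

    def test_shared_noise_floor_limits_averaging(self, baseline_protocol):
        # with the default decomposition the mean-trace sd stays near 1.85e-4
        p = SensorModelParams(seed=3, drift_amplitude=0.0)
        sim = simulate_absorbance_traces(baseline_protocol, p)
        sd = sim.noisy[:, 0, :].mean(axis=0).std(ddof=1)
        assert sd == pytest.approx(1.851e-4, rel=0.2)

    def test_drift_shape(self, baseline_protocol):
        p = SensorModelParams(seed=1, sigma_shared=0.0, sigma_indep=0.0)
        sim = simulate_absorbance_traces(baseline_protocol, p)
        drift = sim.noisy[0, 0, :] - sim.true[0, 0, :]
        expected = p.drift_amplitude * (1 - np.exp(-sim.time / p.drift_tau))
        np.testing.assert_allclose(drift, expected, atol=1e-12)

    def test_determinism(self, six_cycle_protocol, layout):
        p = SensorModelParams(seed=42)
        a = simulate_absorbance_traces(six_cycle_protocol, p)
        b = simulate_absorbance_traces(six_cycle_protocol, p)
        np.testing.assert_array_equal(a.noisy, b.noisy)
        c = simulate_absorbance_traces(six_cycle_protocol, p.replace(seed=43))
        assert not np.array_equal(a.noisy, c.noisy)

    def test_frame_determinism(self, layout):
        tr = make_traces(np.full((6, 3, 3), 0.01), layout)
        f1 = render_frames(tr, layout, pixel_noise_sd=1.0, seed=7)
        f2 = render_frames(tr, layout, pixel_noise_sd=1.0, seed=7)
        np.testing.assert_array_equal(f1, f2)


class TestRendering:
    def test_zero_absorbance_renders_baseline(self, layout, reference_frame):
        for mask in layout.spot_masks():
            np.testing.assert_array_equal(
                reference_frame[mask],
                np.tile(np.asarray(layout.baseline_rgb, dtype=np.uint8), (mask.sum(), 1)),
            )

    def test_log10_2_halves_intensity(self, layout):
        a = np.zeros((6, 3, 1))
        a[:, 0, :] = 0.30103
        frame = render_frames(make_traces(a, layout), layout, pixel_noise_sd=0.0)[0]
        mask = layout.spot_masks()[0]
        assert frame[mask][:, 0].max() == frame[mask][:, 0].min() == 100  # 200 / 2

    def test_nan_absorbance_rejected(self, layout):
        a = np.zeros((6, 3, 1))
        a[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            render_frames(make_traces(a, layout), layout)

    def test_roundtrip_quantization_bound(self, layout, noiseless_params):
        # extraction must recover simulated absorbance within the 8-bit bound
        proto = GasProtocol.alternating([1000.0], 30.0, 60.0, tail_purge=False)
        sim = simulate_absorbance_traces(proto, noiseless_params, layout)
        frames = render_frames(sim, layout, pixel_noise_sd=0.0)
        rois = detect_spots(frames[0])
        traces = compute_absorbance(sim.time, extract_traces(frames, rois))
        err = np.abs(traces.absorbance - sim.noisy)
        bound = 1.0 / (traces.intensity * np.log(10.0))
        assert np.all(err <= bound)

    def test_roundtrip_with_pixel_noise(self, layout, noiseless_params):
        # error within 3x the propagated ROI-mean noise plus quantization
        proto = GasProtocol.alternating([1000.0], 30.0, 60.0, tail_purge=False)
        sim = simulate_absorbance_traces(proto, noiseless_params, layout)
        frames = render_frames(sim, layout, pixel_noise_sd=1.0, seed=5)
        rois = detect_spots(frames[0])
        traces = compute_absorbance(sim.time, extract_traces(frames, rois))
        n_px = min(r.area for r in rois)
        err = np.abs(traces.absorbance - sim.noisy)
        sigma_mean = 1.0 / (traces.intensity * np.log(10.0) * np.sqrt(n_px))
        tol = 3.0 * np.sqrt(2.0) * sigma_mean + 0.5 / (traces.intensity * np.log(10.0))
        assert (err <= tol).mean() > 0.99

    def test_layout_invariants(self):
        with pytest.raises(ValueError, match="overlap"):
            SpotLayout(pitch=20.0, spot_radius=14.0)
        with pytest.raises(ValueError, match="outside"):
            SpotLayout(origin=(5.0, 30.0))
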