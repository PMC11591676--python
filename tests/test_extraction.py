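"""Absorbance computation, array averaging, noise estimation, detrending."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from co2lens import (
    GasProtocol,
    SensorModelParams,
    average_spots,
    compute_absorbance,
    detrend_baseline,
    detrend_series,
    estimate_noise,
    extract_traces,
    improvement_factor,
    simulate_absorbance_traces,
)
from co2lens.spots import SpotROI


def _roi(pixels, spot_id=0):
    pixels = np.asarray(pixels)
    return SpotROI(
        spot_id=spot_id,
        centroid=tuple(pixels.mean(axis=0)),
        radius_equiv=1.0,
        pixel_mask=pixels,
    )


class TestExtract:
    def test_uniform_and_two_pixel_mean(self):
        frames = np.full((2, 4, 4, 3), 100, dtype=np.uint8)
        frames[:, 1, 2, :] = 90
        frames[:, 2, 2, :] = 110
        uniform = extract_traces(frames, [_roi([[0, 0], [0, 1]])])
        np.testing.assert_allclose(uniform, 100.0)
        two = extract_traces(frames, [_roi([[1, 2], [2, 2]])])
        np.testing.assert_allclose(two, 100.0)

    def test_roi_outside_frame_rejected(self):
        frames = np.zeros((1, 4, 4, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="geometry"):
            extract_traces(frames, [_roi([[3, 9]])])


class TestAbsorbance:
    def test_identities(self):
        t = np.arange(3, dtype=float)
        i = np.full((1, 3, 3), 100.0)
        i[0, 0] = [100.0, 50.0, 200.0]
        traces = compute_absorbance(t, i)
        assert traces.absorbance[0, 0, 0] == 0.0
        assert traces.absorbance[0, 0, 1] == pytest.approx(0.30103, abs=1e-5)
        # brightening gives negative absorbance, preserved
        assert traces.absorbance[0, 0, 2] == pytest.approx(-0.30103, abs=1e-5)

    def test_first_frame_convention(self):
        t = np.arange(5, dtype=float)
        i = np.random.default_rng(0).uniform(50, 200, (2, 3, 5))
        traces = compute_absorbance(t, i, i0_frames=1)
        np.testing.assert_allclose(traces.absorbance[:, :, 0], 0.0, atol=1e-12)
        multi = compute_absorbance(t, i, i0_frames=3)
        np.testing.assert_allclose(multi.i0, i[:, :, :3].mean(axis=2))

    def test_nonpositive_intensity_named(self):
        t = np.arange(3, dtype=float)
        i = np.full((2, 3, 3), 100.0)
        i[1, 2, 1] = 0.0
        with pytest.raises(ValueError, match=r"spot 1, channel B, frame 1"):
            compute_absorbance(t, i)

    def test_definition_invariant_checked(self):
        t = np.arange(3, dtype=float)
        traces = compute_absorbance(t, np.full((1, 3, 3), 100.0))
        traces.absorbance[0, 0, 0] = 0.5  # corrupt
        with pytest.raises(ValueError, match="log10"):
            traces.validate()


class TestAverage:
    def test_identity_and_mean(self):
        arr = np.vstack([np.full(4, 0.1), np.full(4, 0.3)])
        np.testing.assert_allclose(average_spots(arr, [0]), 0.1)
        np.testing.assert_allclose(average_spots(arr), 0.2)

    def test_unknown_spot_rejected(self):
        with pytest.raises(KeyError):
            average_spots(np.zeros((2, 4)), [5])

    def test_absorbance_averaging_vs_intensity_averaging(self):
        # averaging absorbance differs from absorbance of the averaged
        # intensity by a small Jensen gap; document its size
        amps = np.array([0.915, 0.955, 0.990, 1.010, 1.045, 1.085])
        a = amps[:, None] * 0.0178 * np.ones((6, 10))
        i = 200.0 * 10.0 ** (-a)
        mean_a = a.mean(axis=0)
        a_of_mean_i = -np.log10(i.mean(axis=0) / 200.0)
        gap = np.abs(mean_a - a_of_mean_i).max()
        assert 0 < gap < 1e-5

    def test_averaging_reduces_independent_noise(self, baseline_protocol):
        # sigma_shared = 0: noise of 6-spot mean converges to sigma_indep/sqrt(6)
        est = []
        for seed in range(1, 11):
            p = SensorModelParams(seed=seed, sigma_shared=0.0)
            sim = simulate_absorbance_traces(baseline_protocol, p)
            avg = average_spots(sim.noisy[:, 0, :])
            est.append(estimate_noise(avg, sim.time))
        assert np.median(est) == pytest.approx(2.82e-4 / np.sqrt(6), rel=0.2)


class TestEstimateNoise:
    def test_constant_and_ramp_give_zero(self):
        t = np.arange(50.0)
        assert estimate_noise(np.full(50, 0.3), t) == pytest.approx(0.0, abs=1e-12)
        assert estimate_noise(0.01 * t + 0.2, t) == pytest.approx(0.0, abs=1e-12)

    def test_known_sigma_recovery(self):
        t = np.arange(300.0)
        est = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = 1e-5 * t + rng.normal(0, 3.17e-4, t.size)
            est.append(estimate_noise(y, t))
        assert np.median(est) == pytest.approx(3.17e-4, rel=0.15)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        a=st.floats(-1, 1, allow_nan=False),
        b=st.floats(-1e-2, 1e-2, allow_nan=False),
    )
    def test_location_and_slope_invariance(self, a, b):
        t = np.arange(60.0)
        y = np.random.default_rng(4).normal(0, 1e-3, t.size)
        base = estimate_noise(y, t)
        shifted = estimate_noise(y + a + b * t, t)
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-15)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            estimate_noise(np.zeros(10))


class TestImprovementFactor:
    def test_printed_noise_pair_gives_1p7(self):
        assert improvement_factor(3.17e-4, 1.85e-4) == pytest.approx(1.71, abs=0.01)

    def test_identity_and_errors(self):
        assert improvement_factor(2.0, 2.0) == 1.0
        with pytest.raises(ValueError):
            improvement_factor(0.0, 1.0)


class TestDetrend:
    def test_none_is_identity(self):
        t = np.arange(100.0)
        y = np.sin(t / 10)
        np.testing.assert_array_equal(detrend_series(y, t, [(0, 50)], method="none"), y)

    def test_exponential_removes_simulated_drift(self):
        p = SensorModelParams(seed=2, sigma_shared=0.0, sigma_indep=0.0)
        proto = GasProtocol.alternating([1000.0] * 3, 200.0, 120.0)
        sim = simulate_absorbance_traces(proto, p)
        avg = average_spots(sim.noisy[:, 0, :])
        corr = detrend_series(avg, sim.time, proto.purge_windows(), "exponential", settle=150.0)
        truth = average_spots(sim.true[:, 0, :])
        # noise-free, so corr - truth is exactly drift minus the fitted model
        resid = corr - truth
        assert np.ptp(resid) < 0.1 * p.drift_amplitude

    def test_linear_preserves_square_wave_amplitude(self):
        t = np.arange(400.0)
        square = np.where((t // 100) % 2 == 1, 0.02, 0.0)
        drift = 1e-5 * t
        purges = [(0, 99), (200, 299)]
        corr = detrend_series(square + drift, t, purges, method="linear")
        delta = corr[t == 150].mean() - corr[t == 50].mean()
        assert delta == pytest.approx(0.02, rel=0.01)

    def test_no_purge_windows_rejected(self):
        with pytest.raises(ValueError, match="purge"):
            detrend_series(np.zeros(100), np.arange(100.0), [], method="linear")

    def test_traces_level_detrend_marks_state(self, six_cycle_protocol):
        p = SensorModelParams(seed=2)
        sim = simulate_absorbance_traces(six_cycle_protocol, p)
        base = np.array([200.0, 160.0, 120.0])
        intensity = base[None, :, None] * 10.0 ** (-sim.noisy)
        traces = compute_absorbance(sim.time, intensity)
        corr = detrend_baseline(traces, six_cycle_protocol, method="linear")
        assert corr.detrended == "linear"
        assert traces.detrended == "none"
        traces.validate()  # raw traces still satisfy the definition
        assert not np.allclose(corr.absorbance, traces.absorbance)
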