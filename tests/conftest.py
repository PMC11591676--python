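import numpy as np
import pytest

from co2lens import (
    GasProtocol,
    Phase,
    SensorModelParams,
    SimulatedTraces,
    SpotLayout,
    render_frames,
)


@pytest.fixture
def default_params():
    return SensorModelParams(seed=1)


@pytest.fixture
def noiseless_params():
    return SensorModelParams(seed=1, sigma_shared=0.0, sigma_indep=0.0, drift_amplitude=0.0)


@pytest.fixture
def uniform_params(noiseless_params):
    """Noiseless and homogeneous: every spot amplitude 1."""
    return noiseless_params.replace(spot_amplitudes=(1.0,) * 6)


@pytest.fixture
def layout():
    return SpotLayout()


@pytest.fixture
def six_cycle_protocol():
    """Replica of the alternating air / 1000 ppm CO2 six-cycle run."""
    return GasProtocol.alternating([1000.0] * 6, purge_duration=120.0, exposure_duration=120.0)


@pytest.fixture
def baseline_protocol():
    """300 s of clean air only: a signal-free baseline."""
    return GasProtocol(phases=(Phase("air", 0.0, 0.0, 300.0),))


@pytest.fixture
def reference_frame(layout):
    """Noise-free rendered frame of the unreacted array (A = 0 everywhere)."""
    sim = SimulatedTraces(
        time=np.array([0.0]),
        true=np.zeros((layout.n_spots, 3, 1)),
        noisy=np.zeros((layout.n_spots, 3, 1)),
        protocol=GasProtocol(phases=(Phase("air", 0.0, 0.0, 1.0),)),
        params=SensorModelParams(seed=0),
    )
    return render_frames(sim, layout, pixel_noise_sd=0.0)[0]


def make_traces(absorbance, layout=None, time=None, seed=0):
    """Wrap an (n_spots, 3, T) absorbance array as SimulatedTraces for rendering."""
    layout = layout or SpotLayout()
    absorbance = np.asarray(absorbance, dtype=float)
    n_t = absorbance.shape[2]
    t = np.arange(n_t, dtype=float) if time is None else time
    return SimulatedTraces(
        time=t,
        true=absorbance,
        noisy=absorbance,
        protocol=GasProtocol(phases=(Phase("air", 0.0, 0.0, float(n_t)),)),
        params=SensorModelParams(seed=seed),
    )
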