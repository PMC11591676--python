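"""Synthetic sensor physics for a lensless colorimetric CO2 array.

Generates ground-truth and noisy absorbance dynamics for a 2 x 3 array of
indicator spots imaged in contact with a CMOS chip, plus rendered 8-bit RGB
frame stacks, so every downstream stage of the pipeline can be exercised
without hardware.

The phenomenological model:

* steady-state response is a Langmuir-type saturation
  ``dA_ss(C) = w_c * dA_max_eff * C / (C + K_half)`` per color channel,
  with an optional metal-organic-framework (MOF) enhancement factor
  multiplying ``dA_max``;
* kinetics are first order with separate response/recovery time constants;
* the noisy trace adds a saturating-exponential LED warm-up drift, a
  shared (light-source) Gaussian noise term common to all spots, and an
  independent per-spot Gaussian term;
* per-spot coating heterogeneity scales each spot's amplitude.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

CHANNELS = ("R", "G", "B")

_AIR = "air"


def channel_index(channel: str) -> int:
    try:
        return CHANNELS.index(channel)
    except ValueError:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")


@dataclass(frozen=True)
class Phase:
    """One protocol phase: a gas delivered at a concentration for a duration."""

    gas_id: str
    concentration: float  # ppm
    start: float  # s
    duration: float  # s

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class GasProtocol:
    """Ordered purge/exposure phases on a uniform frame grid.

    Purge phases carry gas_id "air" at 0 ppm; phases must be time-ordered
    and non-overlapping.  ``flow_lpm`` is an annotation only (chamber flow,
    L/min) and plays no role in the simulation.
    """

    phases: tuple[Phase, ...]
    frame_interval: float = 1.0
    total_duration: float | None = None
    flow_lpm: float = 0.5

    def __post_init__(self):
        phases = tuple(self.phases)
        object.__setattr__(self, "phases", phases)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        prev_end = 0.0
        for ph in phases:
            if ph.concentration < 0:
                raise ValueError(f"negative concentration in phase {ph}")
            if ph.duration <= 0:
                raise ValueError(f"non-positive duration in phase {ph}")
            if ph.start < prev_end - 1e-9:
                raise ValueError("phases overlap or are out of order")
            if ph.gas_id == _AIR and ph.concentration != 0:
                raise ValueError("air (purge) phases must have concentration 0")
            prev_end = ph.end
        if self.total_duration is None:
            object.__setattr__(self, "total_duration", prev_end)
        elif self.total_duration < prev_end - 1e-9:
            raise ValueError("total_duration ends before the last phase")

    @classmethod
    def alternating(
        cls,
        concentrations,
        purge_duration: float,
        exposure_duration: float,
        gas_id: str = "co2",
        frame_interval: float = 1.0,
        tail_purge: bool = True,
    ) -> "GasProtocol":
        """Purge/exposure alternation, one exposure per listed concentration."""
        phases = []
        t = 0.0
        for conc in np.atleast_1d(concentrations):
            phases.append(Phase(_AIR, 0.0, t, purge_duration))
            t += purge_duration
            phases.append(Phase(gas_id, float(conc), t, exposure_duration))
            t += exposure_duration
        if tail_purge:
            phases.append(Phase(_AIR, 0.0, t, purge_duration))
            t += purge_duration
        return cls(phases=tuple(phases), frame_interval=frame_interval, total_duration=t)

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration / self.frame_interval))

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def profile(self):
        """(times, concentration array, gas-id object array), air outside phases."""
        t = self.times()
        conc = np.zeros(t.size)
        gas = np.array([_AIR] * t.size, dtype=object)
        for ph in self.phases:
            m = (t >= ph.start - 1e-9) & (t < ph.end - 1e-9)
            conc[m] = ph.concentration
            gas[m] = ph.gas_id
        return t, conc, gas

    def purge_windows(self) -> list[tuple[float, float]]:
        return [(ph.start, ph.end) for ph in self.phases if ph.concentration == 0]

    def exposure_phases(self) -> list[Phase]:
        return [ph for ph in self.phases if ph.concentration > 0]


def _default_gas_response():
    # interferent amplitude multipliers; the skin-gas panel shows minimal
    # interference so these default to zero but stay configurable
    return {
        "co2": 1.0,
        "acetone": 0.0,
        "nh3": 0.0,
        "ethanol": 0.0,
        "lactate": 0.0,
        "o2": 0.0,
    }


@dataclass(frozen=True)
class SensorModelParams:
    """Phenomenological parameters of the colorimetric response.

    Defaults are anchored so the rendered study conditions reproduce the
    headline figures of merit: a C->0 sensitivity of
    ``dA_max*mof_factor/K_half = 2.1346e-5`` AU/ppm, a t90 of ~50 s, a
    single-spot baseline noise of ~3.17e-4 AU and a 6-spot-average noise of
    ~1.85e-4 AU (shared + independent decomposition), and a 17% spot-to-spot
    amplitude spread.
    """

    dA_max: float = 0.053365  # AU, R channel, without MOF enhancement
    K_half: float = 5000.0  # ppm
    mof_factor: float = 2.0
    mof_enabled: bool = True
    channel_weights: tuple[float, float, float] = (1.0, 0.6, 0.1)
    tau_response: float = 21.71  # s
    tau_recovery: float = 21.71  # s
    sigma_shared: float = 1.45e-4  # AU, common to all spots per sample
    sigma_indep: float = 2.82e-4  # AU, per spot per sample
    drift_amplitude: float = 2e-3  # AU, LED warm-up
    drift_tau: float = 600.0  # s
    spot_amplitudes: tuple[float, ...] = (0.915, 0.955, 0.990, 1.010, 1.045, 1.085)
    gas_response: dict = field(default_factory=_default_gas_response)
    seed: int = 0

    def __post_init__(self):
        if self.K_half <= 0:
            raise ValueError("K_half must be > 0")
        if self.tau_response <= 0 or self.tau_recovery <= 0:
            raise ValueError("time constants must be > 0")
        for name in ("sigma_shared", "sigma_indep", "drift_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        w = self.channel_weights
        if not (w[0] >= w[1] >= w[2] >= 0):
            raise ValueError("channel_weights must satisfy R >= G >= B >= 0")
        if any(a <= 0 for a in self.spot_amplitudes):
            raise ValueError("spot_amplitudes must be > 0")

    @property
    def effective_dA_max(self) -> float:
        return self.dA_max * (self.mof_factor if self.mof_enabled else 1.0)

    @property
    def sensitivity_low_range(self) -> float:
        """Ground-truth dA/dC at C->0 for the R channel, AU/ppm."""
        return self.effective_dA_max / self.K_half

    def replace(self, **kw) -> "SensorModelParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SpotLayout:
    """Geometry and base colors of the 2 x 3 spot array on the imager."""

    rows: int = 2
    cols: int = 3
    spot_radius: float = 14.0  # px
    pitch: float = 42.0  # px, center-to-center
    origin: tuple[float, float] = (26.0, 30.0)  # (row, col) of spot 0 center
    frame_size: tuple[int, int] = (96, 144)  # (height, width)
    baseline_rgb: tuple[float, float, float] = (200.0, 160.0, 120.0)
    background_rgb: tuple[float, float, float] = (60.0, 60.0, 60.0)

    def __post_init__(self):
        if self.pitch <= 2 * self.spot_radius:
            raise ValueError("spots overlap: pitch must exceed 2 * spot_radius")
        h, w = self.frame_size
        for r, c in self.centers():
            if not (
                self.spot_radius <= r <= h - 1 - self.spot_radius
                and self.spot_radius <= c <= w - 1 - self.spot_radius
            ):
                raise ValueError("spot extends outside the frame")

    @property
    def n_spots(self) -> int:
        return self.rows * self.cols

    def centers(self) -> list[tuple[float, float]]:
        """Row-major spot centers, (row, col) pixels, origin top-left."""
        return [
            (self.origin[0] + r * self.pitch, self.origin[1] + c * self.pitch)
            for r in range(self.rows)
            for c in range(self.cols)
        ]

    def spot_masks(self) -> list[np.ndarray]:
        """Boolean (H, W) disk mask per spot, row-major order."""
        h, w = self.frame_size
        rr, cc = np.ogrid[:h, :w]
        masks = []
        for r0, c0 in self.centers():
            masks.append((rr - r0) ** 2 + (cc - c0) ** 2 <= self.spot_radius**2)
        return masks


@dataclass
class SimulatedTraces:
    """Simulated per-spot, per-channel absorbance: ground truth and noisy."""

    time: np.ndarray  # (T,)
    true: np.ndarray  # (n_spots, 3, T) AU
    noisy: np.ndarray  # (n_spots, 3, T) AU
    protocol: GasProtocol
    params: SensorModelParams

    @property
    def n_spots(self) -> int:
        return self.true.shape[0]


def steady_state_response(
    concentration: float,
    params: SensorModelParams,
    channel: str = "R",
    gas_id: str = "co2",
) -> float:
    """Steady-state absorbance change dA_ss(C) for one channel.

    Langmuir-type saturation: zero at C = 0, half the effective amplitude at
    C = K_half, saturating toward ``channel_weight * dA_max_eff``.
    """
    c = float(concentration)
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    w = params.channel_weights[channel_index(channel)]
    g = params.gas_response.get(gas_id, 0.0)
    return w * g * params.effective_dA_max * c / (c + params.K_half)


def simulate_absorbance_traces(
    protocol: GasProtocol,
    params: SensorModelParams,
    layout: SpotLayout | None = None,
) -> SimulatedTraces:
    """Integrate the first-order response to a protocol and add the noise model.

    Ground truth per spot s, channel c follows dA/dt = (dA_ss - A)/tau with
    tau = tau_response while rising and tau_recovery while relaxing, scaled
    by spot_amplitudes[s].  The noisy trace adds LED warm-up drift
    ``drift_amplitude * (1 - exp(-t/drift_tau))``, one shared Gaussian draw
    per (channel, frame) and an independent Gaussian draw per
    (spot, channel, frame).  Fully reproducible from params.seed.
    """
    if layout is not None and layout.n_spots != len(params.spot_amplitudes):
        raise ValueError("layout spot count does not match spot_amplitudes")
    t, conc, gas = protocol.profile()
    n_t = t.size
    n_spots = len(params.spot_amplitudes)
    gmult = np.array([params.gas_response.get(g, 0.0) for g in gas])
    base = params.effective_dA_max * gmult * conc / (conc + params.K_half)  # (T,)
    w = np.asarray(params.channel_weights, dtype=float)
    amps = np.asarray(params.spot_amplitudes, dtype=float)
    target = amps[:, None, None] * w[None, :, None] * base[None, None, :]

    true = np.zeros((n_spots, 3, n_t))
    a = np.zeros((n_spots, 3))
    dt = protocol.frame_interval
    # exact per-step update of the piecewise-constant-target first-order ODE;
    # target held at its left-edge value over each interval
    decay_up = np.exp(-dt / params.tau_response)
    decay_down = np.exp(-dt / params.tau_recovery)
    for n in range(1, n_t):
        tgt = target[:, :, n - 1]
        decay = np.where(tgt > a, decay_up, decay_down)
        a = tgt + (a - tgt) * decay
        true[:, :, n] = a

    rng = np.random.default_rng(params.seed)
    drift = params.drift_amplitude * (1.0 - np.exp(-t / params.drift_tau))
    shared = rng.normal(0.0, params.sigma_shared, size=(3, n_t))
    indep = rng.normal(0.0, params.sigma_indep, size=(n_spots, 3, n_t))
    noisy = true + drift[None, None, :] + shared[None, :, :] + indep
    return SimulatedTraces(time=t, true=true, noisy=noisy, protocol=protocol, params=params)


def render_frames(
    traces: SimulatedTraces,
    layout: SpotLayout,
    pixel_noise_sd: float = 1.0,
    seed: int | None = None,
    which: str = "noisy",
) -> np.ndarray:
    """Render a (T, H, W, 3) uint8 frame stack from absorbance traces.

    Spot pixels in channel c get ``baseline_rgb[c] * 10**(-A_c(t))`` so the
    downstream −log10(I/I0) extraction inverts the rendering exactly;
    background pixels get ``background_rgb``.  Per-pixel Gaussian noise is
    added before rounding (round half to even) and clipping to [0, 255].
    """
    if traces.n_spots != layout.n_spots:
        raise ValueError("trace and layout spot counts differ")
    a = traces.noisy if which == "noisy" else traces.true
    if np.isnan(a).any():
        raise ValueError("NaN absorbance cannot be rendered")
    masks = [np.nonzero(m) for m in layout.spot_masks()]
    h, w = layout.frame_size
    n_t = traces.time.size
    rng = np.random.default_rng(traces.params.seed if seed is None else seed)
    base = np.empty((h, w, 3))
    frames = np.empty((n_t, h, w, 3), dtype=np.uint8)
    bg = np.asarray(layout.background_rgb, dtype=float)
    spot0 = np.asarray(layout.baseline_rgb, dtype=float)
    for n in range(n_t):
        base[:] = bg
        for s, (rr, cc) in enumerate(masks):
            base[rr, cc, :] = spot0 * 10.0 ** (-a[s, :, n])
        img = base
        if pixel_noise_sd > 0:
            img = base + rng.normal(0.0, pixel_noise_sd, size=base.shape)
        frames[n] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return frames


def count_rise_events(series: np.ndarray, tol: float = 1e-9) -> int:
    """Number of contiguous strictly-rising episodes in a (noise-free) series."""
    rising = np.diff(np.asarray(series, dtype=float)) > tol
    if rising.size == 0:
        return 0
    starts = np.flatnonzero(rising & ~np.concatenate(([False], rising[:-1])))
    return int(starts.size)


def count_decay_events(series: np.ndarray, tol: float = 1e-9) -> int:
    return count_rise_events(-np.asarray(series, dtype=float), tol=tol)
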