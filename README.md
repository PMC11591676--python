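# co2lens

Signal-processing and calibration pipeline for **lensless CMOS colorimetric
CO₂ sensor arrays**, plus a synthetic generator of the sensor's physics so
the whole chain can be developed and verified without hardware.

The instrument this package analyzes is a 2 × 3 array of colorimetric
indicator spots (a pH dye + glycine carbamate chemistry, optionally loaded
in a metal–organic framework matrix) printed on a thin PDMS membrane and
adhered directly to the pixels of a CMOS imager — no lens, no focal
distance. CO₂ exposure shifts the dye's color; the imager records RGB
frames; chemistry turns into numbers via per-channel absorbance.

## The model

Per spot and color channel, with `I(t)` the mean ROI intensity and `I₀` the
first-frame reference:

```
A(t) = −log10( I(t) / I₀ )
```

The concentration response is modeled as Langmuir-type saturation with
first-order kinetics:

```
ΔA_ss(C) = w_c · m · ΔA_max · C / (C + K_half),      dA/dt = (ΔA_ss − A)/τ
```

where `m` is the MOF sensitivity-enhancement factor (default 2: "with MOF"
doubles the sensitivity) and `τ ≈ 21.7 s` gives a 90 % response time of
~50 s. Noise has a **shared** component (LED fluctuations common to all
spots, σ ≈ 1.45 × 10⁻⁴ AU) and an **independent** per-spot component
(σ ≈ 2.82 × 10⁻⁴ AU), so a single spot sees ~3.17 × 10⁻⁴ AU while the
6-spot average sees ~1.85 × 10⁻⁴ AU — a ~1.7× noise (and detection-limit)
improvement, deliberately less than the √6 an all-independent model would
give. A saturating-exponential baseline drift emulates LED warm-up.

Figures of merit follow standard chemometrics: low-range sensitivity
`s = ΔA_max / K_half` (AU/ppm), and the 3σ limit of detection
`LOD = 3·σ / s` (≈ 26 ppm under the default conditions).

## Worked example

```python
import numpy as np
from co2lens import (
    GasProtocol, SensorModelParams, average_spots, cycle_delta,
    cycles_from_protocol, detrend_series, estimate_noise,
    fit_saturating, improvement_factor, simulate_absorbance_traces,
)

params = SensorModelParams(seed=1)
protocol = GasProtocol.alternating([100.0, 200.0, 500.0, 1000.0],
                                   purge_duration=200.0, exposure_duration=200.0)
sim = simulate_absorbance_traces(protocol, params)

single = estimate_noise(sim.noisy[0, 0, :], sim.time, window=(0.0, 200.0))
avg = average_spots(sim.noisy[:, 0, :])
array_noise = estimate_noise(avg, sim.time, window=(0.0, 200.0))
print(f"single-spot noise : {single:.3e} AU")
print(f"array-average noise: {array_noise:.3e} AU")
print(f"improvement factor : {improvement_factor(single, array_noise):.2f}x")

corr = detrend_series(avg, sim.time, protocol.purge_windows(),
                      method="exponential", settle=120.0)
cycles = cycles_from_protocol(protocol)
deltas = [cycle_delta(corr, sim.time, cyc) for cyc in cycles]
cal = fit_saturating([cyc.concentration for cyc in cycles], deltas).with_noise(array_noise)
print(f"low-range sensitivity: {cal.sensitivity_low_range:.3e} AU/ppm")
print(f"detection limit (SNR 3): {cal.lod:.1f} ppm")
```

prints

```
single-spot noise : 3.278e-04 AU
array-average noise: 1.801e-04 AU
improvement factor : 1.82x
low-range sensitivity: 2.135e-05 AU/ppm
detection limit (SNR 3): 25.3 ppm
```

The single-spot baseline noise (~3.3 × 10⁻⁴ AU) drops to ~1.8 × 10⁻⁴ AU
after averaging the six spots; combined with the fitted low-range
sensitivity the 3σ rule puts the detection limit near 25 ppm for this seed.

A command-line interface mirrors the stages (`co2lens simulate | detect |
extract | analyze | calibrate | quantify | run`); `co2lens run --seed 1
--out run_out` executes the whole pipeline from rendered frames to a
calibration JSON and writes a `manifest.json` of artifact hashes that is
bit-identical for identical config + seed.

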