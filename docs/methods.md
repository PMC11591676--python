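# Methods

This note documents the models, estimators and numerical choices behind
`co2lens`, and what the synthetic study conditions do and do not establish
about real hardware.

## Sensing model

The package treats the colorimetric chemistry phenomenologically. The
carbamate reaction of CO₂ with glycine releases protons that shift a pH
indicator from purple toward yellow; transmission through each sensing spot
is recorded by the CMOS pixels underneath it. We do not model the
equilibrium chemistry; instead the steady-state absorbance change in
channel c is a Langmuir-type saturation

    ΔA_ss(C) = w_c · m · ΔA_max · C / (C + K_half)

- `ΔA_max` (absorbance units, default 0.053365): saturation amplitude of
  the R channel without matrix enhancement.
- `K_half` (ppm, default 5000): half-saturation concentration. Together
  these set the low-range sensitivity s = m·ΔA_max/K_half =
  2.1346 × 10⁻⁵ AU/ppm, the anchor from which the default detection limit
  follows.
- `m` (`mof_factor`, default 2.0, toggled by `mof_enabled`): sensitivity
  enhancement from loading the indicator in the porous MOF matrix.
- `w_c` (`channel_weights`, default (1, 0.6, 0.1)): per-channel response.
  The R channel responds most and is the analysis channel throughout; B is
  treated as weakly responsive.

A saturating form was chosen because the measured response flattens at
high concentration while remaining near-linear on a log-concentration
axis; no functional form is established for this chemistry, and the
log-linear alternative is provided as a second calibration model.

Kinetics are first order, `dA/dt = (ΔA_ss − A)/τ`, with `tau_response` and
`tau_recovery` both defaulting to 21.71 s so that the 90 % rise time
τ·ln 10 is 50 s, matching the instrument's reported response scale. The
integrator uses the exact per-step update for a piecewise-constant target
(`A ← T + (A−T)·e^(−Δt/τ)`), with the target held at its value at the left
edge of each frame interval, so noise-free traces obey the closed form to
machine precision.

## Noise and drift

The noisy trace adds three terms to the ground truth:

1. **Shared noise** `ε(t) ~ N(0, σ_sh²)`, one draw per channel and frame,
   common to all spots — light-source fluctuation. Default
   σ_sh = 1.45 × 10⁻⁴ AU.
2. **Independent noise** `ε_s(t) ~ N(0, σ_ind²)` per spot — shot/readout
   noise of each ROI. Default σ_ind = 2.82 × 10⁻⁴ AU.
3. **Drift** `d(t) = a·(1 − e^(−t/τ_d))` — LED warm-up, default
   a = 2 × 10⁻³ AU, τ_d = 600 s, common to all spots and channels.

The decomposition is chosen so a single spot carries
√(σ_sh² + σ_ind²) ≈ 3.17 × 10⁻⁴ AU and the six-spot average
√(σ_sh² + σ_ind²/6) ≈ 1.85 × 10⁻⁴ AU: averaging improves noise by ~1.7×,
not √6 ≈ 2.45×. A shared component is the only simple mechanism consistent
with that pair of levels; its split between the two terms is our inference,
not a measured property.

Per-spot coating heterogeneity multiplies each spot's amplitude by
`spot_amplitudes`, default (0.915, 0.955, 0.990, 1.010, 1.045, 1.085) —
mean exactly 1 and range/mean exactly 17 %, the array's reported
spot-to-spot spread. Interferent gases (acetone, NH₃, ethanol, lactate,
O₂) default to zero response amplitude, reflecting minimal
cross-sensitivity; the multipliers are configurable.

## Rendering and extraction

Frames are rendered by inverting the absorbance definition exactly: spot
pixels get `baseline_rgb[c] · 10^(−A_c(t))` plus optional per-pixel
Gaussian noise, rounded half-to-even and clipped to the 8-bit range;
background pixels get `background_rgb`. Spots are sharp disks — no
point-spread or defocus model, which is the idealization lensless contact
imaging approaches but never fully reaches.

Extraction takes the arithmetic mean of each channel over the ROI mask,
and absorbance is `−log10(I/I₀)` with `I₀` from the first frame (the
recording convention; `i0_frames > 1` is offered because a noisy single
reference frame biases every later sample). Negative absorbance
(brightening) is preserved. With an 8-bit quantizer the round trip is
exact to within `1/(I·ln 10)` per sample, which the test suite asserts.

Spot detection thresholds the channel-mean grayscale with Otsu's method,
tries both contrast polarities (indicator vs backlight polarity is not
fixed) and keeps the side whose component count is closer to the expected
grid, filters components by area and circularity `4πA/P²`, and orders the
survivors row-major by centroid. Detection runs on the first frame only
and ROIs are frozen — the membrane is adhered, so no motion model.
Default erosion margin 0.2, circularity minimum 0.6.

## Estimators

- **Baseline noise**: sample standard deviation of the residuals after a
  straight-line fit over a stated signal-free window (≥ 20 samples). The
  linear detrend makes the estimate invariant to location and slope. The
  exact estimator behind reported noise levels on this class of instrument
  is generally unstated; this definition is ours and documented here.
- **Cycle change ΔA**: mean of the last 20 % of the exposure window minus
  the mean of the last 20 % of the preceding purge window (both fractions
  configurable); reported as a magnitude with the signed value available.
  Windows are half-open `[start, end)` so a boundary frame belongs to the
  following phase.
- **Response/recovery time**: t₉₀ from exposure onset (time to reach
  baseline + 0.9·ΔA, linearly interpolated between frames), and the
  symmetric return to within 10 % of baseline after the purge begins. Both
  estimators first apply the same centered 5-sample moving average used by
  the segmenter: a first-passage rule on raw noisy samples crosses early
  with a bias of several seconds at the default noise level, while the
  smoothing shifts noise-free crossings by well under one frame.
- **Segmentation**: 5-sample moving average, discrete derivative centered
  on its median (so steady drift is not an event), onset/offset where the
  derivative exceeds ±6·MAD, events merged within a minimum cycle
  duration, onsets paired with following offsets. When the MAD is at
  floating-point rounding level (ideal noise-free steps) a half-peak
  threshold is used instead. Protocol-derived windows are available and
  preferred when the protocol file exists.
- **Spot variation**: 100·(max − min)/mean of per-spot ΔA. Range-over-mean
  was chosen over CV to match how a "~17 % difference" across six curves
  is naturally read; the statistic is scale-invariant.

## Drift correction

`detrend_baseline` fits the drift model (linear or the saturating
exponential) to **purge-window samples only** and subtracts it from the
whole series; a `settle` parameter (120 s in the pipeline's calibration
path, ≈ 5.5 τ) drops the start of each purge so recovery transients do not
contaminate the fit. Without correction, the warm-up drift biases the
100 ppm cycle's ΔA by up to ~30 % early in a run and shifts t₉₀ by a few
seconds; with it, residual baseline wander is well under 10 % of the drift
amplitude. Corrected absorbance is stored separately from the raw
definition-satisfying series (`detrended` flag), since after subtraction
`A = −log10(I/I₀)` no longer holds sample-wise.

## Calibration and detection limit

The saturating model is fitted by bounded nonlinear least squares
(analytic Jacobian, initialized at `ΔA_max = max ΔA`,
`K_half = median C`, 500-evaluation cap, 1e-14 step/gradient tolerances;
non-convergence raises with the last iterate). Noiseless
model-generated data are recovered to 10⁻⁶ relative over
`ΔA_max ∈ [10⁻³, 1]`, `K_half ∈ [10², 10⁴]`. The log-linear model is OLS
of ΔA on log₁₀ C; for it, `sensitivity_low_range` is the model derivative
at the low end of the calibrated range, `slope/(ln 10 · C_min)`, keeping
the LOD identity defined for both models. R² is computed against the
mean-only null (plain, not adjusted); for degenerate constant data it is
reported as 0.

    LOD = snr_factor · σ / s,   snr_factor = 3

uses the **array-average** noise and the saturating fit's low-range
sensitivity; under the default conditions (σ ≈ 1.85 × 10⁻⁴ AU,
s ≈ 2.13 × 10⁻⁵ AU/ppm) this lands at ≈ 26 ppm. The log-linear slope is
not used for the LOD by default because its per-ppm sensitivity depends on
concentration.

## Problem sizes and reproducibility

The acceptance computations use 300 s baselines and 200–500 s cycles at a
1 s frame interval, 10 replicate seeds for stochastic quantities
(medians reported), and a four-point low-range calibration
(100/200/500/1000 ppm) — sizes at which every statistic above is stable to
a few percent while the full run stays interactive. All randomness flows
from a single integer seed through `numpy.random.default_rng`; identical
seeds give bit-identical traces, frames and artifact hashes.

## Limitations

- The generator reproduces the *statistical structure* the analysis
  assumes (saturation, first-order kinetics, two-component noise, smooth
  drift, amplitude heterogeneity). Real sensors add effects it omits:
  humidity and temperature dependence, indicator aging and photobleaching,
  spatial illumination gradients, motion, and optical blur. Passing tests
  demonstrate the pipeline's correctness on the modeled physics, not
  hardware performance.
- The noise decomposition into shared and independent parts is inferred
  from the averaging gain, not measured.
- Interferent responses are configured, not derived from chemistry; the
  selectivity table documents bounded relative response under those
  settings only.
- The saturating functional form and the operational definitions of t₉₀,
  recovery time and spot variation are this package's choices where the
  field reports numbers without definitions.
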