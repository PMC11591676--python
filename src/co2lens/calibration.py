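"""Concentration-response calibration, detection limit and selectivity.

Two calibration models are supported: a Langmuir-type saturating curve
``dA = dA_max * C / (C + K_half)`` fitted by nonlinear least squares, and an
ordinary least-squares line of dA against log10(C).  The limit of detection
follows the 3-sigma convention, LOD = snr_factor * noise / sensitivity, with
the array-average baseline noise and the low-range (C -> 0) sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import log

import numpy as np
from scipy.optimize import least_squares


class ConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class CalibrationResult:
    """A fitted response model plus the figures of merit derived from it.

    ``params`` is (dA_max, K_half) for the saturating model or
    (slope_per_decade, intercept) for the log-linear model.  When a noise
    level is attached, the identity lod = snr_factor * noise_sigma /
    sensitivity_low_range holds exactly.
    """

    model: str  # "saturating" | "loglinear"
    params: tuple[float, float]
    r_squared: float
    sensitivity_low_range: float  # AU per ppm
    concentration_range: tuple[float, float]
    noise_sigma: float | None = None
    snr_factor: float = 3.0
    lod: float | None = None

    def __post_init__(self):
        lo, hi = self.concentration_range
        if lo > hi:
            raise ValueError("concentration_range endpoints must be ordered")
        if self.lod is not None:
            expected = self.snr_factor * self.noise_sigma / self.sensitivity_low_range
            if not np.isclose(self.lod, expected, rtol=1e-12):
                raise ValueError("lod violates lod = snr * sigma / sensitivity")

    def with_noise(self, noise_sigma: float, snr_factor: float = 3.0) -> "CalibrationResult":
        """Attach a noise level and the implied detection limit."""
        lod = detection_limit(noise_sigma, self.sensitivity_low_range, snr_factor)
        return replace(self, noise_sigma=noise_sigma, snr_factor=snr_factor, lod=lod)


@dataclass(frozen=True)
class SelectivityEntry:
    gas_id: str
    test_concentration: float
    delta_A: float
    relative_response: float  # dA_gas / dA_CO2


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def _check_points(concentrations, deltas, need_positive: bool):
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(deltas, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValueError("concentrations and deltas must be matching 1-D arrays")
    if need_positive and np.any(c <= 0):
        raise ValueError("log-scale calibration requires all concentrations > 0")
    if len(set(c[c > 0])) < 3:
        raise ValueError("need at least 3 distinct positive concentrations")
    return c, y


def fit_saturating(concentrations, deltas) -> CalibrationResult:
    """Least-squares fit of the saturating model dA = dA_max * C / (C + K_half).

    Initialized at dA_max = max dA, K_half = median C; analytic Jacobian;
    iteration capped at 500 evaluations with 1e-14 step/gradient tolerances.
    The low-range sensitivity is dA_max / K_half.
    """
    c, y = _check_points(concentrations, deltas, need_positive=False)

    def resid(p):
        return p[0] * c / (c + p[1]) - y

    def jac(p):
        f = c / (c + p[1])
        return np.column_stack([f, -p[0] * c / (c + p[1]) ** 2])

    p0 = np.array([max(y.max(), 1e-12), max(np.median(c[c > 0]), 1e-9)])
    res = least_squares(
        resid,
        p0,
        jac=jac,
        bounds=([1e-12, 1e-9], [np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=500,
    )
    if not res.success:
        raise ConvergenceError(
            f"saturating fit did not converge: {res.message}", tuple(res.x)
        )
    da_max, k_half = float(res.x[0]), float(res.x[1])
    fitted = da_max * c / (c + k_half)
    return CalibrationResult(
        model="saturating",
        params=(da_max, k_half),
        r_squared=_r_squared(y, fitted),
        sensitivity_low_range=da_max / k_half,
        concentration_range=(float(c.min()), float(c.max())),
    )


def fit_loglinear(concentrations, deltas) -> CalibrationResult:
    """OLS of dA on log10(C): slope per decade, intercept, plain R^2.

    The low-range sensitivity (AU/ppm) is the model derivative at the low
    end of the calibrated range, slope / (ln 10 * C_min), so the LOD
    identity remains well defined for this model too.
    """
    c, y = _check_points(concentrations, deltas, need_positive=True)
    x = np.log10(c)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    c_min = float(c.min())
    return CalibrationResult(
        model="loglinear",
        params=(float(slope), float(intercept)),
        r_squared=_r_squared(y, fitted),
        sensitivity_low_range=float(slope) / (log(10.0) * c_min),
        concentration_range=(c_min, float(c.max())),
    )


def detection_limit(noise_sigma: float, sensitivity: float, snr_factor: float = 3.0) -> float:
    """3-sigma detection limit: snr_factor * noise / sensitivity, in ppm."""
    if sensitivity <= 0:
        raise ValueError("sensitivity must be > 0")
    if noise_sigma < 0:
        raise ValueError("noise must be >= 0")
    return snr_factor * noise_sigma / sensitivity


def invert_concentration(delta_A: float, cal: CalibrationResult) -> float:
    """Closed-form inverse of the fitted model; values below 0 clip to 0."""
    if cal.model == "saturating":
        da_max, k_half = cal.params
        if delta_A >= da_max:
            raise ValueError(
                f"delta_A {delta_A} is at or above the fitted saturation {da_max}"
            )
        return max(k_half * delta_A / (da_max - delta_A), 0.0)
    if cal.model == "loglinear":
        slope, intercept = cal.params
        if slope == 0:
            raise ValueError("log-linear model with zero slope cannot be inverted")
        return max(10.0 ** ((delta_A - intercept) / slope), 0.0)
    raise ValueError(f"unknown model {cal.model!r}")


def sensitivity_ratio(cal_a: CalibrationResult, cal_b: CalibrationResult) -> float:
    """Ratio of low-range sensitivities a/b (e.g. MOF-on vs MOF-off)."""
    if cal_a.model != cal_b.model:
        raise ValueError(f"model mismatch: {cal_a.model} vs {cal_b.model}")
    return cal_a.sensitivity_low_range / cal_b.sensitivity_low_range


def selectivity_table(gas_responses: dict, co2_delta_A: float) -> list[SelectivityEntry]:
    """Relative responses of interferent gases against the CO2 reference.

    ``gas_responses`` maps gas_id -> (test_concentration_ppm, delta_A).
    Entries are returned sorted by gas_id.
    """
    if co2_delta_A <= 0:
        raise ValueError("CO2 reference response must be > 0")
    entries = [
        SelectivityEntry(
            gas_id=gas,
            test_concentration=float(conc),
            delta_A=float(da),
            relative_response=float(da) / co2_delta_A,
        )
        for gas, (conc, da) in gas_responses.items()
    ]
    return sorted(entries, key=lambda e: e.gas_id)
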