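"""Cycle segmentation and per-cycle response metrics.

A run alternates air purges with gas exposures; each cycle contributes an
absorbance change dA (plateau minus preceding baseline), a response time
(t90 from exposure onset) and a recovery time (return to within 10% of the
pre-exposure baseline).  Cycles can be taken from the protocol file or
recovered from the signal itself by derivative thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import GasProtocol

UNDEFINED = float("nan")


@dataclass(frozen=True)
class Cycle:
    """One purge/exposure pair; the purge precedes the exposure."""

    cycle_id: int
    purge_window: tuple[float, float]
    exposure_window: tuple[float, float]
    concentration: float | None = None
    gas_id: str | None = None

    def __post_init__(self):
        p0, p1 = self.purge_window
        e0, e1 = self.exposure_window
        if not (p0 <= p1 <= e0 <= e1):
            raise ValueError("cycle windows must be ordered purge then exposure")


@dataclass
class CycleResponse:
    """Per-cycle summary over the array."""

    cycle_id: int
    exposure_window: tuple[float, float]
    purge_window: tuple[float, float]
    concentration: float | None
    delta_A_spots: np.ndarray  # per-spot magnitudes
    delta_A_mean: float  # of the array-average trace
    response_time_t90: float
    recovery_time: float


def cycles_from_protocol(protocol: GasProtocol) -> list[Cycle]:
    """One Cycle per exposure phase, paired with the preceding purge."""
    cycles = []
    prev_end = 0.0
    prev_purge: tuple[float, float] | None = None
    for ph in protocol.phases:
        if ph.concentration == 0:
            prev_purge = (ph.start, ph.end)
        else:
            purge = prev_purge if prev_purge is not None else (prev_end, ph.start)
            cycles.append(
                Cycle(
                    cycle_id=len(cycles),
                    purge_window=purge,
                    exposure_window=(ph.start, ph.end),
                    concentration=ph.concentration,
                    gas_id=ph.gas_id,
                )
            )
            prev_purge = None
        prev_end = ph.end
    return cycles


def _smooth(series: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return np.asarray(series, dtype=float)
    kernel = np.ones(width) / width
    padded = np.pad(np.asarray(series, dtype=float), width // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: len(series)]


def _run_starts(mask: np.ndarray) -> np.ndarray:
    return np.flatnonzero(mask & ~np.concatenate(([False], mask[:-1])))


def _merge(events: np.ndarray, min_gap: int) -> list[int]:
    merged: list[int] = []
    for e in events:
        if not merged or e - merged[-1] >= min_gap:
            merged.append(int(e))
    return merged


def segment_cycles(
    series: np.ndarray,
    frame_interval: float,
    min_cycle_duration: float = 20.0,
    k: float = 6.0,
    smooth_width: int = 5,
) -> list[Cycle]:
    """Recover purge/exposure cycles from the signal alone.

    The series is smoothed (moving average), differentiated, and exposure
    onsets/offsets are marked where the derivative exceeds +/- k * MAD of
    the derivative.  Events closer than ``min_cycle_duration`` are merged;
    each onset is paired with the next offset.  A constant series yields an
    empty list; an unpaired trailing onset is dropped with a warning.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2 * min_cycle_duration / frame_interval:
        raise ValueError("series too short for the requested minimum cycle duration")
    d = np.diff(_smooth(series, smooth_width))
    if d.size == 0 or np.ptp(d) == 0:  # constant slope: no transitions
        return []
    d = d - np.median(d)  # a steady drift slope is not an event
    mad = np.median(np.abs(d))
    scale = np.abs(d).max()
    # below rounding noise the MAD carries no information; fall back to a
    # half-peak threshold (the ideal noise-free square-wave case)
    thr = k * mad if mad > 1e-9 * scale else 0.5 * scale
    if thr == 0:
        return []
    min_gap = max(int(round(min_cycle_duration / frame_interval)), 1)
    onsets = _merge(_run_starts(d > thr), min_gap)
    offsets = _merge(_run_starts(d < -thr), min_gap)

    t_of = lambda i: (i + 1) * frame_interval  # diff index i spans frames i..i+1
    cycles: list[Cycle] = []
    prev_off_t = 0.0
    oi = 0
    for onset in onsets:
        while oi < len(offsets) and offsets[oi] <= onset:
            oi += 1
        if oi >= len(offsets):
            warnings.warn("unpaired trailing exposure onset dropped", stacklevel=2)
            break
        cycles.append(
            Cycle(
                cycle_id=len(cycles),
                purge_window=(prev_off_t, t_of(onset)),
                exposure_window=(t_of(onset), t_of(offsets[oi])),
            )
        )
        prev_off_t = t_of(offsets[oi])
        oi += 1
    return cycles


def _window_samples(series, time, window, tail_frac):
    # half-open [start, t1): the sample at t1 belongs to the next phase
    t0, t1 = window
    start = t1 - tail_frac * (t1 - t0)
    sel = (time >= start) & (time < t1)
    return series[sel]


def cycle_delta(
    series: np.ndarray,
    time: np.ndarray,
    cycle: Cycle,
    baseline_frac: float = 0.2,
    plateau_frac: float = 0.2,
    signed: bool = False,
) -> float:
    """Absorbance change of one cycle: plateau minus preceding baseline.

    Plateau = mean of the last ``plateau_frac`` of the exposure window;
    baseline = mean of the last ``baseline_frac`` of the preceding purge.
    Returned as a magnitude by default (signed=True keeps the raw sign).
    """
    series = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)
    base = _window_samples(series, time, cycle.purge_window, baseline_frac)
    plat = _window_samples(series, time, cycle.exposure_window, plateau_frac)
    if base.size < 3 or plat.size < 3:
        raise ValueError(
            f"cycle {cycle.cycle_id}: need >= 3 samples in each window "
            f"(got {base.size} baseline, {plat.size} plateau)"
        )
    delta = float(plat.mean() - base.mean())
    return delta if signed else abs(delta)


def _first_crossing(series, time, start_t, level, rising: bool):
    sel = time >= start_t
    t = time[sel]
    y = series[sel]
    above = y >= level if rising else y <= level
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return UNDEFINED
    i = idx[0]
    if i == 0:
        return float(t[0])
    # linear interpolation between bracketing samples
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    frac = (level - y0) / (y1 - y0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def response_time(
    series: np.ndarray,
    time: np.ndarray,
    cycle: Cycle,
    threshold: float = 0.9,
    baseline_frac: float = 0.2,
    smooth_width: int = 5,
) -> float:
    """t90: time from exposure onset to first reaching baseline + 0.9 * dA.

    The series is lightly smoothed (same width as segmentation) before the
    threshold crossing, which is located by linear interpolation.  Returns
    NaN (undefined) if the level is never reached.
    """
    time = np.asarray(time, dtype=float)
    sm = _smooth(np.asarray(series, dtype=float), smooth_width)
    base = _window_samples(sm, time, cycle.purge_window, baseline_frac).mean()
    delta = cycle_delta(sm, time, cycle, baseline_frac=baseline_frac, signed=True)
    level = base + threshold * delta
    t_cross = _first_crossing(sm, time, cycle.exposure_window[0], level, rising=delta >= 0)
    if np.isnan(t_cross):
        return UNDEFINED
    return t_cross - cycle.exposure_window[0]


def recovery_time(
    series: np.ndarray,
    time: np.ndarray,
    cycle: Cycle,
    fraction: float = 0.1,
    baseline_frac: float = 0.2,
    smooth_width: int = 5,
) -> float:
    """Time from purge onset (exposure end) back to within ``fraction`` * dA
    of the pre-exposure baseline; NaN if the series never recovers."""
    time = np.asarray(time, dtype=float)
    sm = _smooth(np.asarray(series, dtype=float), smooth_width)
    base = _window_samples(sm, time, cycle.purge_window, baseline_frac).mean()
    delta = cycle_delta(sm, time, cycle, baseline_frac=baseline_frac, signed=True)
    level = base + fraction * delta
    purge_on = cycle.exposure_window[1]
    t_cross = _first_crossing(sm, time, purge_on, level, rising=delta < 0)
    if np.isnan(t_cross):
        return UNDEFINED
    return t_cross - purge_on


def spot_variation(per_spot_deltas) -> float:
    """Spot-to-spot spread of the array: 100 * (max - min) / mean, percent."""
    deltas = np.asarray(per_spot_deltas, dtype=float)
    if deltas.size < 2:
        raise ValueError("need at least 2 per-spot values")
    mean = deltas.mean()
    if mean <= 0:
        raise ValueError("mean response must be > 0")
    return float(100.0 * (deltas.max() - deltas.min()) / mean)


def summarize_cycles(
    traces_absorbance: np.ndarray,
    time: np.ndarray,
    cycles: list[Cycle],
    baseline_frac: float = 0.2,
    plateau_frac: float = 0.2,
) -> list[CycleResponse]:
    """Per-cycle summary from an (n_spots, T) absorbance matrix (one channel)."""
    mean_trace = traces_absorbance.mean(axis=0)
    out = []
    for cyc in cycles:
        per_spot = np.array(
            [
                cycle_delta(traces_absorbance[s], time, cyc, baseline_frac, plateau_frac)
                for s in range(traces_absorbance.shape[0])
            ]
        )
        out.append(
            CycleResponse(
                cycle_id=cyc.cycle_id,
                exposure_window=cyc.exposure_window,
                purge_window=cyc.purge_window,
                concentration=cyc.concentration,
                delta_A_spots=per_spot,
                delta_A_mean=cycle_delta(mean_trace, time, cyc, baseline_frac, plateau_frac),
                response_time_t90=response_time(mean_trace, time, cyc),
                recovery_time=recovery_time(mean_trace, time, cyc),
            )
        )
    return out
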