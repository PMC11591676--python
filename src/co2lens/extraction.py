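"""Intensity and absorbance time series from frame stacks.

Absorbance follows the transmission convention of contact imaging:
``A = -log10(I / I0)`` per color channel, with the reference intensity I0
taken from the first frame (optionally an average of the first few frames).
Brightening yields negative absorbance and is preserved, never clipped.
All intensities stay on the native 0-255 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import CHANNELS, GasProtocol, channel_index
from .spots import SpotROI


@dataclass
class AbsorbanceTraces:
    """Per-spot, per-channel intensity and absorbance series.

    ``intensity`` and ``absorbance`` are (n_spots, 3, T); ``i0`` is the
    (n_spots, 3) reference intensity averaged over the first ``i0_frames``
    frames.  The definition A = -log10(I/I0) holds for every stored sample
    unless the series has been drift-corrected (``detrended`` != "none"),
    in which case ``absorbance`` carries the corrected values and the raw
    identity no longer applies.
    """

    time: np.ndarray
    intensity: np.ndarray
    absorbance: np.ndarray
    i0: np.ndarray
    i0_frames: int = 1
    spot_ids: tuple[int, ...] = ()
    detrended: str = "none"
    channels: tuple[str, ...] = field(default=CHANNELS, repr=False)

    def __post_init__(self):
        if not self.spot_ids:
            self.spot_ids = tuple(range(self.intensity.shape[0]))
        if self.detrended == "none":
            self.validate()

    @property
    def n_spots(self) -> int:
        return self.intensity.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        """Assert the absorbance definition on every stored sample."""
        if np.any(self.intensity <= 0):
            raise ValueError("all intensities must be > 0")
        expected = -np.log10(self.intensity / self.i0[:, :, None])
        if not np.allclose(self.absorbance, expected, atol=atol):
            raise ValueError("absorbance does not satisfy A = -log10(I/I0)")

    def spot_index(self, spot_id: int) -> int:
        try:
            return self.spot_ids.index(spot_id)
        except ValueError:
            raise KeyError(f"unknown spot id {spot_id}; have {self.spot_ids}")


def extract_traces(frames: np.ndarray, rois: list[SpotROI]) -> np.ndarray:
    """Mean ROI intensity per spot, channel and frame -> (n_spots, 3, T).

    Each sample is the arithmetic mean of the channel values over the ROI's
    pixel mask; channels are ordered R, G, B.
    """
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[3] < 3:
        raise ValueError("frames must be (T, H, W, 3)")
    n_t, h, w = frames.shape[:3]
    if n_t < 1:
        raise ValueError("need at least one frame")
    out = np.empty((len(rois), 3, n_t))
    for s, roi in enumerate(rois):
        mask = roi.pixel_mask
        if mask.shape[0] == 0:
            raise ValueError(f"spot {roi.spot_id} has an empty mask")
        if mask[:, 0].max() >= h or mask[:, 1].max() >= w or mask.min() < 0:
            raise ValueError(f"spot {roi.spot_id} mask lies outside the frame geometry")
        px = frames[:, mask[:, 0], mask[:, 1], :3].astype(float)  # (T, N, 3)
        out[s] = px.mean(axis=1).T
    return out


def compute_absorbance(
    time: np.ndarray,
    intensity: np.ndarray,
    i0_frames: int = 1,
    spot_ids: tuple[int, ...] = (),
) -> AbsorbanceTraces:
    """Convert intensity series to absorbance against a first-frames reference.

    I0 is the per-spot, per-channel mean of the first ``i0_frames`` samples
    (default 1: the first-frame convention, under which A(0) = 0 exactly).
    """
    intensity = np.asarray(intensity, dtype=float)
    time = np.asarray(time, dtype=float)
    if intensity.ndim != 3 or intensity.shape[2] != time.size:
        raise ValueError("intensity must be (n_spots, 3, T) matching time")
    if not 1 <= i0_frames <= time.size:
        raise ValueError("i0_frames must be in [1, series length]")
    bad = np.argwhere(intensity <= 0)
    if bad.size:
        s, c, t = bad[0]
        sid = spot_ids[s] if spot_ids else s
        raise ValueError(
            f"non-positive intensity at spot {sid}, channel {CHANNELS[c]}, frame {t}"
        )
    i0 = intensity[:, :, :i0_frames].mean(axis=2)
    absorbance = -np.log10(intensity / i0[:, :, None])
    return AbsorbanceTraces(
        time=time,
        intensity=intensity,
        absorbance=absorbance,
        i0=i0,
        i0_frames=int(i0_frames),
        spot_ids=tuple(spot_ids),
    )


def average_spots(traces, spot_ids=None, channel: str = "R") -> np.ndarray:
    """Pointwise arithmetic mean of the selected spots' absorbance series.

    Averaging is done on absorbance, not intensity.  ``traces`` may be an
    AbsorbanceTraces or a plain (n_spots, T) array (then ``spot_ids`` are
    row indices and ``channel`` is ignored).
    """
    if isinstance(traces, AbsorbanceTraces):
        idx = (
            list(range(traces.n_spots))
            if spot_ids is None
            else [traces.spot_index(s) for s in spot_ids]
        )
        if not idx:
            raise ValueError("need at least one spot id")
        return traces.absorbance[idx, channel_index(channel), :].mean(axis=0)
    arr = np.asarray(traces, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected an (n_spots, T) array")
    if spot_ids is None:
        idx = list(range(arr.shape[0]))
    else:
        idx = list(spot_ids)
        if any(i < 0 or i >= arr.shape[0] for i in idx):
            raise KeyError(f"unknown spot id in {idx}")
    if not idx:
        raise ValueError("need at least one spot id")
    return arr[idx].mean(axis=0)


def estimate_noise(
    series: np.ndarray,
    time: np.ndarray | None = None,
    window: tuple[float, float] | None = None,
    min_samples: int = 20,
) -> float:
    """Baseline noise: sd of residuals after a linear detrend of a window.

    The straight-line fit removes slow drift slope, so the estimate is
    invariant to adding a + b*t.  The window should cover a signal-free
    baseline and must contain at least ``min_samples`` samples.
    """
    series = np.asarray(series, dtype=float)
    t = np.arange(series.size, dtype=float) if time is None else np.asarray(time, float)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        series, t = series[sel], t[sel]
    if series.size < min_samples:
        raise ValueError(f"window has {series.size} samples; need >= {min_samples}")
    coef = np.polyfit(t, series, 1)
    resid = series - np.polyval(coef, t)
    return float(resid.std(ddof=1))


def improvement_factor(noise_single: float, noise_average: float) -> float:
    """Noise (hence detection-limit) improvement from array averaging."""
    if noise_single <= 0 or noise_average <= 0:
        raise ValueError("noise levels must be > 0")
    return float(noise_single) / float(noise_average)


def _exp_drift(t, amp, tau, offset):
    return amp * (1.0 - np.exp(-t / tau)) + offset


def detrend_series(
    series: np.ndarray,
    time: np.ndarray,
    purge_windows: list[tuple[float, float]],
    method: str = "linear",
    settle: float = 0.0,
) -> np.ndarray:
    """Fit a drift model to purge-window samples and subtract it everywhere.

    ``settle`` drops the first seconds of each purge window from the fit so
    recovery transients do not contaminate the drift estimate.  Methods:
    none (identity), linear, exponential (saturating LED warm-up shape).
    """
    series = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)
    if method == "none":
        return series.copy()
    if not purge_windows:
        raise ValueError("no purge windows to fit the drift model on")
    sel = np.zeros(time.size, dtype=bool)
    for t0, t1 in purge_windows:
        sel |= (time >= t0 + settle) & (time <= t1)
    if sel.sum() < 3:
        raise ValueError("purge windows contain too few samples for a drift fit")
    tp, yp = time[sel], series[sel]
    if method == "linear":
        model = np.polyval(np.polyfit(tp, yp, 1), time)
    elif method == "exponential":
        span = max(time[-1] - time[0], 1.0)
        p0 = (yp[-1] - yp[0], span / 3.0, yp[0])
        popt, _ = curve_fit(
            _exp_drift,
            tp,
            yp,
            p0=p0,
            bounds=([-1.0, 1e-3, -1.0], [1.0, 1e7, 1.0]),
            maxfev=10000,
        )
        model = _exp_drift(time, *popt)
    else:
        raise ValueError(f"unknown detrend method {method!r}")
    return series - model


def detrend_baseline(
    traces: AbsorbanceTraces,
    protocol: GasProtocol,
    method: str = "linear",
    settle: float = 0.0,
) -> AbsorbanceTraces:
    """Drift-correct every spot/channel series using the protocol's purge
    windows; returns a new AbsorbanceTraces with corrected absorbance and
    the raw intensities untouched."""
    if method == "none":
        return traces
    windows = protocol.purge_windows()
    if not windows:
        raise ValueError("protocol has no purge windows")
    corrected = np.empty_like(traces.absorbance)
    for s in range(traces.n_spots):
        for c in range(3):
            corrected[s, c] = detrend_series(
                traces.absorbance[s, c], traces.time, windows, method=method, settle=settle
            )
    return replace(traces, absorbance=corrected, detrended=method)
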