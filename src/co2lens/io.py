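"""File formats: frame stacks (TIFF / PNG directory), traces CSV, protocol
and ROI JSON.  Every writer is deterministic (sorted JSON keys, LF endings,
shortest exact float repr) so artifact hashes are stable, and every
read(write(x)) round trip reproduces the in-memory object exactly."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .extraction import AbsorbanceTraces
from .spots import SpotROI
from .synthetic import CHANNELS, GasProtocol, Phase, SimulatedTraces, SpotLayout


class FrameReadError(RuntimeError):
    pass


# ---------------------------------------------------------------- frames


def write_frames(path, frames: np.ndarray) -> None:
    """Write a (T, H, W, 3) uint8 stack as multi-page TIFF (``.tif``/``.tiff``)
    or as a directory of zero-padded PNG frames."""
    frames = np.asarray(frames)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frames, photometric="rgb")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:06d}.png", frame)


def read_frames(path) -> np.ndarray:
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise FrameReadError(f"no frame_*.png files in {path}")
        return np.stack([iio.imread(f) for f in files])
    frames = []
    # tifffile reports a broken IFD chain (truncation) only through its
    # logger, so listen for it to honor the error contract
    records: list[str] = []

    class _Capture(logging.Handler):
        def emit(self, record):
            records.append(record.getMessage())

    handler = _Capture()
    tlog = logging.getLogger("tifffile")
    tlog.addHandler(handler)
    try:
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                try:
                    frames.append(page.asarray())
                except Exception as exc:
                    raise FrameReadError(
                        f"truncated TIFF {path}: last readable frame is {i - 1}"
                    ) from exc
    except FrameReadError:
        raise
    except Exception as exc:
        raise FrameReadError(f"cannot read TIFF {path}: {exc}") from exc
    finally:
        tlog.removeHandler(handler)
    if any("invalid page offset" in msg for msg in records):
        raise FrameReadError(
            f"truncated TIFF {path}: last readable frame is {len(frames) - 1}"
        )
    if not frames:
        raise FrameReadError(f"no frames in {path}")
    stack = np.stack(frames)
    if stack.ndim == 3:  # single RGB page
        stack = stack[None]
    return stack


# ---------------------------------------------------------------- JSON helpers


def _write_json(path, obj) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


def _read_json(path):
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------- protocol


def write_protocol(path, protocol: GasProtocol) -> None:
    _write_json(
        path,
        {
            "frame_interval": protocol.frame_interval,
            "total_duration": protocol.total_duration,
            "flow_lpm": protocol.flow_lpm,
            "phases": [
                {
                    "gas_id": ph.gas_id,
                    "concentration": ph.concentration,
                    "start": ph.start,
                    "duration": ph.duration,
                }
                for ph in protocol.phases
            ],
        },
    )


def read_protocol(path) -> GasProtocol:
    try:
        obj = _read_json(path)
        return GasProtocol(
            phases=tuple(
                Phase(p["gas_id"], p["concentration"], p["start"], p["duration"])
                for p in obj["phases"]
            ),
            frame_interval=obj["frame_interval"],
            total_duration=obj.get("total_duration"),
            flow_lpm=obj.get("flow_lpm", 0.5),
        )
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed protocol file {path}: {exc}") from exc


# ---------------------------------------------------------------- ROIs


def _rle_encode(mask: np.ndarray) -> list[list[int]]:
    """Row-wise run-length encoding of an (N, 2) pixel list: [row, col0, length]."""
    runs = []
    order = np.lexsort((mask[:, 1], mask[:, 0]))
    px = mask[order]
    for row in np.unique(px[:, 0]):
        cols = px[px[:, 0] == row, 1]
        start = prev = int(cols[0])
        for c in cols[1:]:
            c = int(c)
            if c == prev + 1:
                prev = c
                continue
            runs.append([int(row), start, prev - start + 1])
            start = prev = c
        runs.append([int(row), start, prev - start + 1])
    return runs


def _rle_decode(runs: list[list[int]]) -> np.ndarray:
    coords = [(row, col) for row, col0, length in runs for col in range(col0, col0 + length)]
    return np.asarray(coords, dtype=np.intp)


def write_rois(path, rois: list[SpotROI]) -> None:
    _write_json(
        path,
        [
            {
                "spot_id": roi.spot_id,
                "centroid": list(roi.centroid),
                "radius_equiv": roi.radius_equiv,
                "mask_rle": _rle_encode(roi.pixel_mask),
            }
            for roi in rois
        ],
    )


def read_rois(path) -> list[SpotROI]:
    try:
        return [
            SpotROI(
                spot_id=obj["spot_id"],
                centroid=tuple(obj["centroid"]),
                radius_equiv=obj["radius_equiv"],
                pixel_mask=_rle_decode(obj["mask_rle"]),
            )
            for obj in _read_json(path)
        ]
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed ROI file {path}: {exc}") from exc


# ---------------------------------------------------------------- traces CSV


def write_traces(path, traces: AbsorbanceTraces) -> None:
    """Long-format CSV: time_s, spot_id, channel, intensity, absorbance, i0.

    Floats are written with their shortest exact repr, so reading the file
    back reproduces the object bit for bit.  ``i0_frames`` and the detrend
    state travel in a leading comment line.
    """
    rows = []
    for s, sid in enumerate(traces.spot_ids):
        for c, ch in enumerate(CHANNELS):
            for n, t in enumerate(traces.time):
                rows.append(
                    (t, sid, ch, traces.intensity[s, c, n], traces.absorbance[s, c, n], traces.i0[s, c])
                )
    df = pd.DataFrame(rows, columns=["time_s", "spot_id", "channel", "intensity", "absorbance", "i0"])
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# i0_frames={traces.i0_frames} detrended={traces.detrended}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_traces(path) -> AbsorbanceTraces:
    """Read a traces CSV (header-keyed; column order is irrelevant)."""
    i0_frames, detrended = 1, "none"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            key, _, val = tok.partition("=")
            if key == "i0_frames":
                i0_frames = int(val)
            elif key == "detrended":
                detrended = val
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"time_s", "spot_id", "channel", "intensity", "absorbance", "i0"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"traces CSV {path} is missing columns: {sorted(missing)}")
    time = np.sort(df["time_s"].unique())
    spot_ids = tuple(int(s) for s in np.sort(df["spot_id"].unique()))
    n_s, n_t = len(spot_ids), time.size
    intensity = np.empty((n_s, 3, n_t))
    absorbance = np.empty((n_s, 3, n_t))
    i0 = np.empty((n_s, 3))
    df = df.sort_values(["spot_id", "channel", "time_s"])
    for s, sid in enumerate(spot_ids):
        for c, ch in enumerate(CHANNELS):
            sub = df[(df["spot_id"] == sid) & (df["channel"] == ch)]
            if len(sub) != n_t:
                raise ValueError(
                    f"traces CSV {path}: spot {sid} channel {ch} has {len(sub)} rows, expected {n_t}"
                )
            intensity[s, c] = sub["intensity"].to_numpy()
            absorbance[s, c] = sub["absorbance"].to_numpy()
            i0[s, c] = sub["i0"].iloc[0]
    return AbsorbanceTraces(
        time=time,
        intensity=intensity,
        absorbance=absorbance,
        i0=i0,
        i0_frames=i0_frames,
        spot_ids=spot_ids,
        detrended=detrended,
    )


def write_simulated_traces(path, traces: SimulatedTraces, layout: SpotLayout | None = None) -> None:
    """Simulator ground-truth CSV: time_s, spot_id, channel, intensity,
    absorbance_true, absorbance_noisy (intensity from the layout's baseline)."""
    layout = layout if layout is not None else SpotLayout()
    base = np.asarray(layout.baseline_rgb, dtype=float)
    rows = []
    for s in range(traces.n_spots):
        for c, ch in enumerate(CHANNELS):
            inten = base[c] * 10.0 ** (-traces.noisy[s, c])
            for n, t in enumerate(traces.time):
                rows.append((t, s, ch, inten[n], traces.true[s, c, n], traces.noisy[s, c, n]))
    df = pd.DataFrame(
        rows,
        columns=["time_s", "spot_id", "channel", "intensity", "absorbance_true", "absorbance_noisy"],
    )
    with open(path, "w", newline="\n") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")
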