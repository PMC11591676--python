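"""End-to-end orchestration: simulate -> detect -> extract -> analyze ->
calibrate, with a hash manifest so identical config + seed yields an
identical artifact set."""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np

from . import io as co2io
from .calibration import fit_loglinear, fit_saturating
from .config import RunConfig
from .extraction import (
    average_spots,
    compute_absorbance,
    detrend_baseline,
    estimate_noise,
    extract_traces,
)
from .response import cycles_from_protocol, segment_cycles, summarize_cycles
from .spots import detect_spots, shrink_roi
from .synthetic import GasProtocol, render_frames, simulate_absorbance_traces

log = logging.getLogger("co2lens")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_protocol(config: RunConfig) -> GasProtocol:
    p = config["protocol"]
    if p["file"]:
        return co2io.read_protocol(p["file"])
    return GasProtocol.alternating(
        p["concentrations"],
        purge_duration=p["purge_duration"],
        exposure_duration=p["exposure_duration"],
        gas_id=p["gas_id"],
        frame_interval=p["frame_interval"],
    )


def _validate_inputs(config: RunConfig) -> None:
    if config["protocol"]["file"] and not Path(config["protocol"]["file"]).exists():
        raise FileNotFoundError(f"protocol file not found: {config['protocol']['file']}")
    if not config["simulate"]["enabled"]:
        raise FileNotFoundError("simulate stage disabled but no acquisition source exists")
    if not config["detect"]["enabled"]:
        roi_file = config["detect"]["roi_file"]
        if not roi_file or not Path(roi_file).exists():
            raise FileNotFoundError(f"detect disabled and ROI file not found: {roi_file!r}")


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute the configured stages; returns the results bundle.

    Artifacts (frames, ROI JSON, traces CSV, cycles JSON, calibration JSON)
    are written under ``out_dir`` together with ``manifest.json`` listing a
    SHA-256 per artifact plus the config hash and seed.
    """
    _validate_inputs(config)
    out = Path(out_dir if out_dir is not None else config["run"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    bundle: dict = {}

    def stage(name):
        log.info("stage %s", name)
        t0 = _time.perf_counter()
        return lambda: log.info("stage %s done in %.2fs", name, _time.perf_counter() - t0)

    # -------- simulate
    try:
        done = stage("simulate")
        protocol = _build_protocol(config)
        params = config.sensor_params()
        layout = config.layout()
        sim = simulate_absorbance_traces(protocol, params, layout)
        co2io.write_protocol(out / "protocol.json", protocol)
        artifacts["protocol.json"] = out / "protocol.json"
        co2io.write_simulated_traces(out / "traces_true.csv", sim, layout)
        artifacts["traces_true.csv"] = out / "traces_true.csv"
        if config["simulate"]["frames"]:
            frames = render_frames(
                sim, layout, pixel_noise_sd=config["simulate"]["pixel_noise_sd"]
            )
            co2io.write_frames(out / "frames.tif", frames)
            artifacts["frames.tif"] = out / "frames.tif"
        else:
            frames = None
        bundle.update(protocol=protocol, params=params, layout=layout, simulated=sim)
        done()
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("simulate", exc) from exc

    # -------- detect
    try:
        done = stage("detect")
        d = config["detect"]
        if d["enabled"] and frames is not None:
            rois = detect_spots(
                frames[0],
                expected_rows=layout.rows,
                expected_cols=layout.cols,
                min_area=d["min_area"],
                max_area=d["max_area"],
                circularity_min=d["circularity_min"],
            )
            if d["margin_fraction"] > 0:
                rois = [shrink_roi(r, d["margin_fraction"]) for r in rois]
        elif d["roi_file"]:
            rois = co2io.read_rois(d["roi_file"])
        else:
            rois = None
        if rois is not None:
            co2io.write_rois(out / "rois.json", rois)
            artifacts["rois.json"] = out / "rois.json"
        bundle["rois"] = rois
        done()
    except Exception as exc:
        raise StageError("detect", exc) from exc

    # -------- extract
    try:
        done = stage("extract")
        e = config["extract"]
        if frames is not None and bundle["rois"] is not None:
            intensity = extract_traces(frames, bundle["rois"])
            traces = compute_absorbance(sim.time, intensity, i0_frames=e["i0_frames"])
        else:
            # traces-only run: carry the simulated absorbance forward
            base = np.asarray(layout.baseline_rgb, dtype=float)
            intensity = base[None, :, None] * 10.0 ** (-sim.noisy)
            traces = compute_absorbance(sim.time, intensity, i0_frames=e["i0_frames"])
        if e["detrend"] != "none":
            traces = detrend_baseline(
                traces, protocol, method=e["detrend"], settle=e["detrend_settle"]
            )
        co2io.write_traces(out / "traces.csv", traces)
        artifacts["traces.csv"] = out / "traces.csv"
        bundle["traces"] = traces
        done()
    except Exception as exc:
        raise StageError("extract", exc) from exc

    # -------- analyze
    try:
        done = stage("analyze")
        a = config["analyze"]
        r_abs = traces.absorbance[:, 0, :]  # R channel drives the analysis
        mean_trace = average_spots(traces, channel="R")
        if a["windows"] == "signal":
            cycles = segment_cycles(
                mean_trace, protocol.frame_interval, min_cycle_duration=a["min_cycle_duration"]
            )
        else:
            cycles = cycles_from_protocol(protocol)
        responses = summarize_cycles(
            r_abs, traces.time, cycles, a["baseline_frac"], a["plateau_frac"]
        )
        cyc_json = [
            {
                "cycle_id": r.cycle_id,
                "exposure_window": list(r.exposure_window),
                "purge_window": list(r.purge_window),
                "concentration": r.concentration,
                "delta_A_spots": list(map(float, r.delta_A_spots)),
                "delta_A_mean": r.delta_A_mean,
                "response_time_t90": r.response_time_t90,
                "recovery_time": r.recovery_time,
            }
            for r in responses
        ]
        _write_json(out / "cycles.json", {"seed": config.seed, "cycles": cyc_json})
        artifacts["cycles.json"] = out / "cycles.json"
        bundle["cycles"] = responses
        done()
    except Exception as exc:
        raise StageError("analyze", exc) from exc

    # -------- calibrate
    try:
        done = stage("calibrate")
        c = config["calibrate"]
        concs = [r.concentration for r in bundle["cycles"] if r.concentration]
        cal = None
        if c["enabled"] and len(set(concs)) >= 3:
            deltas = [r.delta_A_mean for r in bundle["cycles"] if r.concentration]
            fit = fit_saturating if c["model"] == "saturating" else fit_loglinear
            cal = fit(concs, deltas)
            purge0 = protocol.purge_windows()[0]
            noise = estimate_noise(mean_trace, traces.time, window=purge0)
            cal = cal.with_noise(noise, snr_factor=c["snr_factor"])
            _write_json(
                out / "calibration.json",
                {
                    "model": cal.model,
                    "params": list(cal.params),
                    "r_squared": cal.r_squared,
                    "sensitivity_low_range": cal.sensitivity_low_range,
                    "noise_sigma": cal.noise_sigma,
                    "snr_factor": cal.snr_factor,
                    "lod_ppm": cal.lod,
                    "concentration_range": list(cal.concentration_range),
                    "seed": config.seed,
                },
            )
            artifacts["calibration.json"] = out / "calibration.json"
        bundle["calibration"] = cal
        done()
    except Exception as exc:
        raise StageError("calibrate", exc) from exc

    manifest = {
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "version": config["run"]["version"],
        "artifacts": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    _write_json(out / "manifest.json", manifest)
    bundle["manifest"] = manifest
    return bundle


def _write_json(path, obj) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")
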