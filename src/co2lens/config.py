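"""Run configuration: every stage default in one TOML-serializable object.

Unknown keys are rejected on load so typos fail loudly; serialization is
deterministic (sections and keys in schema order) and round-trips losslessly
through TOML.
"""

from __future__ import annotations

import copy
import hashlib
import tomllib
from pathlib import Path

from .synthetic import SensorModelParams, SpotLayout

_VERSION = "0.1.0"

DEFAULTS = {
    "run": {"seed": 0, "out_dir": "run_out", "version": _VERSION},
    "protocol": {
        "file": "",  # JSON protocol path; empty -> build from fields below
        "concentrations": [1000.0] * 6,
        "purge_duration": 120.0,
        "exposure_duration": 120.0,
        "gas_id": "co2",
        "frame_interval": 1.0,
        "humidity_rh": 85.0,  # annotation only
    },
    "sensor": {
        "dA_max": 0.053365,
        "K_half": 5000.0,
        "mof_factor": 2.0,
        "mof_enabled": True,
        "channel_weights": [1.0, 0.6, 0.1],
        "tau_response": 21.71,
        "tau_recovery": 21.71,
        "sigma_shared": 1.45e-4,
        "sigma_indep": 2.82e-4,
        "drift_amplitude": 2e-3,
        "drift_tau": 600.0,
        "spot_amplitudes": [0.915, 0.955, 0.990, 1.010, 1.045, 1.085],
    },
    "layout": {
        "rows": 2,
        "cols": 3,
        "spot_radius": 14.0,
        "pitch": 42.0,
        "origin": [26.0, 30.0],
        "frame_size": [96, 144],
        "baseline_rgb": [200.0, 160.0, 120.0],
        "background_rgb": [60.0, 60.0, 60.0],
    },
    "simulate": {"enabled": True, "frames": True, "pixel_noise_sd": 1.0},
    "detect": {
        "enabled": True,
        "roi_file": "",
        "min_area": 50.0,
        "max_area": 5000.0,
        "circularity_min": 0.6,
        "margin_fraction": 0.2,
    },
    "extract": {"i0_frames": 1, "detrend": "none", "detrend_settle": 0.0},
    "analyze": {
        "windows": "protocol",  # "protocol" | "signal"
        "baseline_frac": 0.2,
        "plateau_frac": 0.2,
        "min_cycle_duration": 20.0,
    },
    "calibrate": {"enabled": True, "model": "saturating", "snr_factor": 3.0},
}


class RunConfig:
    """Validated nested mapping of pipeline settings."""

    def __init__(self, data: dict | None = None):
        self.data = copy.deepcopy(DEFAULTS)
        if data:
            self._merge(data)

    def _merge(self, overrides: dict) -> None:
        for section, values in overrides.items():
            if section not in self.data:
                raise KeyError(f"unknown config section [{section}]")
            if not isinstance(values, dict):
                raise ValueError(f"config section [{section}] must be a table")
            for key, val in values.items():
                if key not in self.data[section]:
                    raise KeyError(f"unknown config key {section}.{key}")
                self.data[section][key] = val

    def __getitem__(self, section: str) -> dict:
        return self.data[section]

    @property
    def seed(self) -> int:
        return int(self.data["run"]["seed"])

    def sensor_params(self, seed: int | None = None) -> SensorModelParams:
        s = self.data["sensor"]
        return SensorModelParams(
            dA_max=s["dA_max"],
            K_half=s["K_half"],
            mof_factor=s["mof_factor"],
            mof_enabled=s["mof_enabled"],
            channel_weights=tuple(s["channel_weights"]),
            tau_response=s["tau_response"],
            tau_recovery=s["tau_recovery"],
            sigma_shared=s["sigma_shared"],
            sigma_indep=s["sigma_indep"],
            drift_amplitude=s["drift_amplitude"],
            drift_tau=s["drift_tau"],
            spot_amplitudes=tuple(s["spot_amplitudes"]),
            seed=self.seed if seed is None else seed,
        )

    def layout(self) -> SpotLayout:
        l = self.data["layout"]
        return SpotLayout(
            rows=l["rows"],
            cols=l["cols"],
            spot_radius=l["spot_radius"],
            pitch=l["pitch"],
            origin=tuple(l["origin"]),
            frame_size=tuple(l["frame_size"]),
            baseline_rgb=tuple(l["baseline_rgb"]),
            background_rgb=tuple(l["background_rgb"]),
        )

    # ------------------------------------------------------------ TOML

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls(tomllib.load(fh))

    def to_toml(self) -> str:
        lines = []
        for section, values in self.data.items():
            lines.append(f"[{section}]")
            for key, val in values.items():
                lines.append(f"{key} = {_toml_value(val)}")
            lines.append("")
        return "\n".join(lines)

    def write_toml(self, path) -> None:
        Path(path).write_text(self.to_toml(), newline="\n")

    def sha256(self) -> str:
        return hashlib.sha256(self.to_toml().encode()).hexdigest()


def _toml_value(val) -> str:
    if isinstance(val, bool):
        return "true" if val else "false"
    if isinstance(val, (int, float)):
        return repr(val)
    if isinstance(val, str):
        return '"' + val.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(val, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in val) + "]"
    raise TypeError(f"cannot serialize {type(val).__name__} to TOML")
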