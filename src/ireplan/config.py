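"""TOML run configuration: parsing, validation, serialization, builders.

Keys carry their units as suffixes (``…_cm``, ``…_V``, ``…_V_per_cm``) so a
config file is unambiguous without the manual.  ``loads``/``dumps`` round-
trip exactly at the dict level; the emitter covers the subset of TOML the
schema uses (scalar keys, nested tables, arrays of tables).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .conductivity import ConductivityModel
from .errors import ConfigurationError
from .geometry import ElectrodeConfig, HydrogelGeometry, make_well_geometry, place_electrodes
from .planning import ActivationPlan, PulseProtocol

DEFAULTS = {
    "geometry": {"plate_format": 24, "coculture": False, "grid_spacing_cm": 0.01},
    "conductivity": {"form": "constant", "sigma_S_per_m": 0.027},
    "electrodes": {"layout": "pair", "spacing_cm": 0.8, "radius_cm": 0.0455},
    "plan": {"activations": [{"pair": ["E1", "E2"], "amplitude_V": 1100.0, "n_pulses": 100}]},
    "sweep": {"e_min_V_per_cm": 200.0, "e_max_V_per_cm": 1200.0, "step_V_per_cm": 1.0},
    "thresholds": {"exp_V_per_cm": 544.0, "rep_V_per_cm": 800.0},
    "recovery": {"true_threshold_V_per_cm": 544.0, "noise_cv": 0.05, "n_samples": 9},
    "run": {"seed": 42},
}


def _merge(defaults: dict, given: dict, path="") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in given:
            gval = given[key]
            if isinstance(dval, dict) and isinstance(gval, dict):
                out[key] = _merge(dval, gval, f"{path}{key}.")
            else:
                out[key] = gval
        else:
            out[key] = dval
    for key in given:
        if key not in defaults:
            raise ConfigurationError(f"unknown config key: {path}{key}")
    return out


@dataclass
class RunConfig:
    """Validated run configuration with builders for the model objects."""

    data: dict = dc_field(default_factory=lambda: _merge(DEFAULTS, {}))

    @classmethod
    def loads(cls, text: str) -> "RunConfig":
        try:
            raw = tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigurationError(f"invalid TOML: {exc}") from exc
        return cls(data=_merge(DEFAULTS, raw))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.loads(Path(path).read_text())

    def dumps(self) -> str:
        return dumps_toml(self.data)

    # -- builders -------------------------------------------------------

    def conductivity_model(self) -> ConductivityModel:
        c = self.data["conductivity"]
        if c["form"] == "constant":
            return ConductivityModel.constant(float(c["sigma_S_per_m"]))
        if c["form"] == "field_dependent":
            return ConductivityModel.liver_field_dependent(
                sigma0=float(c.get("sigma0_S_per_m", 0.4)),
                sigmaf=float(c.get("sigmaf_S_per_m", 1.6)),
                e_center_V_per_cm=float(c.get("e_center_V_per_cm", 500.0)),
                e_width_V_per_cm=float(c.get("e_width_V_per_cm", 100.0)),
            )
        raise ConfigurationError(f"unknown conductivity form {c['form']!r}")

    def build_geometry(self, grid_spacing_cm: float | None = None) -> HydrogelGeometry:
        g = self.data["geometry"]
        return make_well_geometry(
            int(g["plate_format"]),
            coculture=bool(g["coculture"]),
            grid_spacing_cm=float(grid_spacing_cm or g["grid_spacing_cm"]),
            conductivity=self.conductivity_model(),
        )

    def build_electrodes(self, geometry: HydrogelGeometry) -> ElectrodeConfig:
        e = self.data["electrodes"]
        return place_electrodes(
            geometry,
            e["layout"],
            float(e["spacing_cm"]),
            electrode_radius_cm=float(e["radius_cm"]),
        )

    def build_plan(self) -> ActivationPlan:
        acts = []
        for a in self.data["plan"]["activations"]:
            proto = PulseProtocol(
                amplitude_V=float(a["amplitude_V"]),
                n_pulses=int(a["n_pulses"]),
                pulse_width_us=float(a.get("pulse_width_us", 100.0)),
                frequency_Hz=float(a.get("frequency_Hz", 1.0)),
            )
            acts.append((tuple(a["pair"]), proto))
        return ActivationPlan(acts)

    @property
    def sweep_params(self) -> tuple:
        s = self.data["sweep"]
        return (
            float(s["e_min_V_per_cm"]),
            float(s["e_max_V_per_cm"]),
            float(s["step_V_per_cm"]),
        )

    @property
    def thresholds(self) -> tuple:
        t = self.data["thresholds"]
        return float(t["exp_V_per_cm"]), float(t["rep_V_per_cm"])

    @property
    def seed(self) -> int:
        return int(self.data["run"]["seed"])


def _fmt_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, list):
        return "[" + ", ".join(_fmt_value(x) for x in v) + "]"
    raise ConfigurationError(f"cannot serialize value of type {type(v).__name__}")


def dumps_toml(data: dict, prefix: str = "") -> str:
    """Serialize the config-schema subset of TOML."""
    lines = []
    scalars = {k: v for k, v in data.items() if not isinstance(v, (dict, list)) or (
        isinstance(v, list) and not any(isinstance(x, dict) for x in v)
    )}
    tables = {k: v for k, v in data.items() if isinstance(v, dict)}
    array_tables = {
        k: v
        for k, v in data.items()
        if isinstance(v, list) and any(isinstance(x, dict) for x in v)
    }
    for k, v in scalars.items():
        lines.append(f"{k} = {_fmt_value(v)}")
    for k, v in tables.items():
        name = f"{prefix}{k}"
        lines.append(f"\n[{name}]")
        lines.append(dumps_toml(v, prefix=name + "."))
    for k, v in array_tables.items():
        name = f"{prefix}{k}"
        for item in v:
            lines.append(f"\n[[{name}]]")
            lines.append(dumps_toml(item, prefix=name + "."))
    return "\n".join(line for line in lines if line != "")
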