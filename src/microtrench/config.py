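"""Run configuration: YAML with explicit units, validated into SI objects.

Every physical quantity in a config file carries an explicit unit string
("700 um", "3.5 cP", "600 dyn/cm2"); internally everything is SI.  Unknown
keys are rejected so typos fail loudly.  ``dump_config(load_config(p))``
round-trips to an identical configuration.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .flow import FlowConditions
from .geometry import ChannelSpec, FluidProperties, TrenchDesign, \
    make_trench_design
from .wss import WSSBandThresholds

__all__ = ["RunConfig", "ConfigError", "load_config", "loads_config",
           "dump_config", "config_hash"]


class ConfigError(ValueError):
    pass


# unit -> (SI factor, dimension tag)
_UNITS = {
    "m": (1.0, "length"), "mm": (1e-3, "length"), "cm": (1e-2, "length"),
    "um": (1e-6, "length"), "µm": (1e-6, "length"), "in": (0.0254, "length"),
    "Pa.s": (1.0, "viscosity"), "Pa*s": (1.0, "viscosity"),
    "mPa.s": (1e-3, "viscosity"), "cP": (1e-3, "viscosity"),
    "kg/m3": (1.0, "density"), "g/cm3": (1e3, "density"),
    "m/s": (1.0, "velocity"), "cm/s": (1e-2, "velocity"),
    "mm/s": (1e-3, "velocity"),
    "dyn/cm2": (1.0, "stress"), "dynes/cm2": (1.0, "stress"),
    "Pa": (10.0, "stress"),        # stress config values are kept in dyn/cm2
    "deg": (1.0, "angle"), "rad": (180.0 / math.pi, "angle"),
    "s": (1.0, "time"), "min": (60.0, "time"), "h": (3600.0, "time"),
}


def parse_quantity(value, dimension: str, key: str) -> float:
    """Parse '700 um' style strings (or bare numbers, taken as SI/native)."""
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise ConfigError(f"{key}: expected 'number unit' string, got {value!r}")
    parts = value.split()
    if len(parts) != 2:
        raise ConfigError(f"{key}: expected 'number unit', got {value!r}")
    try:
        num = float(parts[0])
    except ValueError as exc:
        raise ConfigError(f"{key}: bad number in {value!r}") from exc
    unit = parts[1]
    if unit not in _UNITS:
        raise ConfigError(f"{key}: unknown unit {unit!r}")
    factor, dim = _UNITS[unit]
    if dim != dimension:
        raise ConfigError(f"{key}: unit {unit!r} is a {dim}, expected {dimension}")
    return num * factor


def _check_keys(d: dict, allowed: set[str], where: str):
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; "
                          f"allowed: {sorted(allowed)}")


@dataclass
class RunConfig:
    """Validated, SI-unit run description."""

    design: TrenchDesign | None
    channel: ChannelSpec
    fluid: FluidProperties
    flow: FlowConditions
    thresholds: WSSBandThresholds = field(default_factory=WSSBandThresholds)
    region: str = "patterned"
    resolution: str = "coarse"
    tol: float = 1e-6
    max_iter: int = 40
    deposition: dict | None = None
    output_dir: str = "out"
    seed: int = 0

    def to_dict(self) -> dict:
        d: dict = {"geometry": {"channel": {
            "clear_height": f"{self.channel.clear_height * 1e3:.9g} mm",
            "entrance_length": f"{self.channel.entrance_length * 1e3:.9g} mm",
            "exit_length": f"{self.channel.exit_length * 1e3:.9g} mm",
        }}}
        if self.design is not None:
            d["geometry"]["design"] = {
                "kind": self.design.kind,
                "height": f"{self.design.height * 1e6:.9g} um",
                "width": f"{self.design.width * 1e6:.9g} um",
                "draft_angle": f"{self.design.draft_angle_deg:.9g} deg",
                "gap": f"{self.design.gap * 1e6:.9g} um",
                "n_trenches": self.design.n_trenches,
            }
        d["fluid"] = {"viscosity": f"{self.fluid.viscosity * 1e3:.9g} cP",
                      "density": f"{self.fluid.density:.9g} kg/m3"}
        fl: dict = {"inlet_profile": self.flow.inlet_profile}
        if self.flow.target_bulk_wss is not None:
            fl["target_bulk_wss"] = f"{self.flow.target_bulk_wss:.9g} dyn/cm2"
        else:
            fl["inlet_mean_velocity"] = f"{self.flow.inlet_mean_velocity:.9g} m/s"
        d["flow"] = fl
        d["objective"] = {"lower": f"{self.thresholds.lower:.9g} dyn/cm2",
                          "upper": f"{self.thresholds.upper:.9g} dyn/cm2",
                          "region": self.region}
        d["solver"] = {"resolution": self.resolution, "tol": self.tol,
                       "max_iter": self.max_iter}
        if self.deposition is not None:
            d["deposition"] = dict(self.deposition)
        d["output"] = {"directory": self.output_dir}
        d["seed"] = self.seed
        return d


_TOP = {"geometry", "fluid", "flow", "objective", "solver", "deposition",
        "output", "seed"}


def loads_config(text: str) -> RunConfig:
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP, "top level")

    geo = raw.get("geometry", {})
    _check_keys(geo, {"design", "channel"}, "geometry")
    ch = geo.get("channel", {})
    _check_keys(ch, {"clear_height", "entrance_length", "exit_length"},
                "geometry.channel")
    channel = ChannelSpec(
        clear_height=parse_quantity(ch.get("clear_height", "0.508 mm"),
                                    "length", "clear_height"),
        entrance_length=parse_quantity(ch.get("entrance_length", "1.5 mm"),
                                       "length", "entrance_length"),
        exit_length=parse_quantity(ch.get("exit_length", "2 mm"), "length",
                                   "exit_length"),
    )
    design = None
    if "design" in geo and geo["design"] is not None:
        dz = geo["design"]
        _check_keys(dz, {"kind", "height", "width", "draft_angle", "gap",
                         "n_trenches"}, "geometry.design")
        try:
            design = make_trench_design(
                dz.get("kind", "trapezoidal"),
                parse_quantity(dz["height"], "length", "design.height"),
                parse_quantity(dz["width"], "length", "design.width"),
                parse_quantity(dz.get("draft_angle", "0 deg"), "angle",
                               "design.draft_angle"),
                parse_quantity(dz.get("gap", "0 um"), "length", "design.gap"),
                int(dz.get("n_trenches", 3)),
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    fl = raw.get("fluid", {})
    _check_keys(fl, {"viscosity", "density"}, "fluid")
    fluid = FluidProperties(
        viscosity=parse_quantity(fl.get("viscosity", "3.5 cP"), "viscosity",
                                 "viscosity"),
        density=parse_quantity(fl.get("density", "1050 kg/m3"), "density",
                               "density"),
    )

    fw = raw.get("flow", {})
    _check_keys(fw, {"target_bulk_wss", "inlet_mean_velocity",
                     "inlet_profile"}, "flow")
    kwargs: dict = {"inlet_profile": fw.get("inlet_profile", "developed")}
    if "target_bulk_wss" in fw:
        kwargs["target_bulk_wss"] = parse_quantity(
            fw["target_bulk_wss"], "stress", "target_bulk_wss")
    if "inlet_mean_velocity" in fw:
        kwargs["inlet_mean_velocity"] = parse_quantity(
            fw["inlet_mean_velocity"], "velocity", "inlet_mean_velocity")
    if "target_bulk_wss" not in fw and "inlet_mean_velocity" not in fw:
        kwargs["target_bulk_wss"] = 600.0
    try:
        flow = FlowConditions(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    ob = raw.get("objective", {})
    _check_keys(ob, {"lower", "upper", "region"}, "objective")
    thresholds = WSSBandThresholds(
        lower=parse_quantity(ob.get("lower", "10 dyn/cm2"), "stress", "lower"),
        upper=parse_quantity(ob.get("upper", "50 dyn/cm2"), "stress", "upper"),
    )
    region = ob.get("region", "patterned")

    sv = raw.get("solver", {})
    _check_keys(sv, {"resolution", "tol", "max_iter"}, "solver")

    dep = raw.get("deposition")
    if dep is not None:
        _check_keys(dep, {"coating_map", "default_coating", "t_end",
                          "n_steps", "c_inlet", "rates"}, "deposition")
        dep = dict(dep)
        if "t_end" in dep:
            dep["t_end"] = parse_quantity(dep["t_end"], "time", "t_end")

    out = raw.get("output", {})
    _check_keys(out, {"directory"}, "output")

    return RunConfig(
        design=design, channel=channel, fluid=fluid, flow=flow,
        thresholds=thresholds, region=region,
        resolution=sv.get("resolution", "coarse"),
        tol=float(sv.get("tol", 1e-6)), max_iter=int(sv.get("max_iter", 40)),
        deposition=dep, output_dir=out.get("directory", "out"),
        seed=int(raw.get("seed", 0)),
    )


def load_config(path) -> RunConfig:
    return loads_config(Path(path).read_text())


def dump_config(cfg: RunConfig, path=None) -> str:
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(cfg: RunConfig) -> str:
    """sha256 of the canonical serialized config (provenance stamp)."""
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:16]
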