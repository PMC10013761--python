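"""Structured run configuration with explicit physical units.

Config files are YAML with four sections (``medium``, ``cavity``,
``particle``, ``run``).  Every dimensioned quantity must carry an explicit
unit suffix ("67.52 mm", "1.6 MHz"); values are normalised to SI on load.
Unknown keys are hard errors so typos cannot silently fall back to defaults.
An empty file is valid and yields the documented defaults: water at
c = 1500 m/s, f = 1.6 MHz, p0 = 1 MPa, 30-um cells at 1050 kg/m^3, and a
67.5-mm cavity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from .errors import ConfigError, InvalidParameterError, UnitError, UnknownKeyError
from .forces import CELL_COMPRESSIBILITY, ParticleSpec
from .medium import CavityConfig, Medium

__all__ = ["RunSettings", "RunConfig", "load_config", "parse_quantity"]

_UNIT_TABLES = {
    "length": {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "μm": 1e-6,
               "µm": 1e-6, "nm": 1e-9},
    "frequency": {"Hz": 1.0, "kHz": 1e3, "MHz": 1e6, "GHz": 1e9},
    "pressure": {"Pa": 1.0, "kPa": 1e3, "MPa": 1e6},
    "time": {"s": 1.0, "ms": 1e-3, "us": 1e-6, "μs": 1e-6, "min": 60.0},
    "density": {"kg/m3": 1.0, "kg/m^3": 1.0, "g/cm3": 1e3, "g/cm^3": 1e3},
    "viscosity": {"Pa.s": 1.0, "Pa*s": 1.0, "mPa.s": 1e-3, "mPa*s": 1e-3},
    "compressibility": {"1/Pa": 1.0, "/Pa": 1.0, "1/MPa": 1e-6},
    "speed": {"m/s": 1.0, "mm/s": 1e-3},
    "acceleration": {"m/s2": 1.0, "m/s^2": 1.0},
}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(\S+)\s*$")


def parse_quantity(value, dimension: str, key: str = "?") -> float:
    """Parse "1.6 MHz"-style strings to SI floats for a given dimension."""
    table = _UNIT_TABLES[dimension]
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        raise UnitError(
            f"config key {key!r} needs an explicit unit suffix "
            f"(one of {sorted(table)}), got bare number {value!r}"
        )
    if not isinstance(value, str):
        raise UnitError(f"config key {key!r}: cannot parse {value!r} as a quantity")
    m = _QUANTITY_RE.match(value)
    if not m:
        raise UnitError(f"config key {key!r}: cannot parse {value!r} as 'number unit'")
    number, unit = m.groups()
    if unit not in table:
        raise UnitError(
            f"config key {key!r}: unknown unit {unit!r} for {dimension} "
            f"(expected one of {sorted(table)})"
        )
    try:
        return float(number) * table[unit]
    except ValueError as exc:
        raise UnitError(f"config key {key!r}: bad numeric part in {value!r}") from exc


@dataclass(frozen=True)
class RunSettings:
    """Integration and bookkeeping defaults for a tracing run."""

    duration: float = 1.0
    dt: float = 1e-3
    mode: str = "overdamped"
    seed: int = 0
    gravity: bool = True
    settle_tol: float = 5e-6
    capture_radius: float = 60e-6
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("overdamped", "inertial"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.duration <= 0 or self.dt <= 0:
            raise InvalidParameterError("duration and dt must be > 0")


@dataclass(frozen=True)
class RunConfig:
    medium: Medium = dc_field(default_factory=Medium.water)
    cavity: CavityConfig = dc_field(default_factory=CavityConfig)
    particle: ParticleSpec = dc_field(default_factory=ParticleSpec.cell)
    run: RunSettings = dc_field(default_factory=RunSettings)

    def as_dict(self) -> dict:
        """JSON-serialisable view of the resolved configuration (SI units)."""
        return {
            "medium": {
                "density_kg_m3": self.medium.density,
                "sound_speed_m_s": self.medium.sound_speed,
                "dynamic_viscosity_pa_s": self.medium.dynamic_viscosity,
                "compressibility_1_pa": self.medium.compressibility,
            },
            "cavity": {
                "height_m": self.cavity.height,
                "drive_frequency_hz": self.cavity.drive_frequency,
                "pressure_amplitude_pa": self.cavity.pressure_amplitude,
                "actuator_radius_m": self.cavity.actuator_radius,
                "radial_envelope_width_m": self.cavity.radial_envelope_width,
                "vessel_inner_radius_m": self.cavity.vessel_inner_radius,
            },
            "particle": {
                "radius_m": self.particle.radius,
                "density_kg_m3": self.particle.density,
                "compressibility_1_pa": self.particle.compressibility,
                "rigid": self.particle.rigid,
            },
            "run": {
                "duration_s": self.run.duration,
                "dt_s": self.run.dt,
                "mode": self.run.mode,
                "seed": self.run.seed,
                "gravity": self.run.gravity,
                "settle_tol_m": self.run.settle_tol,
                "capture_radius_m": self.run.capture_radius,
                "log_level": self.run.log_level,
            },
        }


# key -> (dimension or plain type) per section
_SCHEMA: dict[str, dict[str, str | type]] = {
    "medium": {
        "density": "density",
        "sound_speed": "speed",
        "dynamic_viscosity": "viscosity",
        "compressibility": "compressibility",
    },
    "cavity": {
        "height": "length",
        "drive_frequency": "frequency",
        "pressure_amplitude": "pressure",
        "actuator_radius": "length",
        "radial_envelope_width": "length",
        "vessel_inner_radius": "length",
    },
    "particle": {
        "diameter": "length",
        "density": "density",
        "compressibility": "compressibility",
        "rigid": bool,
    },
    "run": {
        "duration": "time",
        "dt": "time",
        "mode": str,
        "seed": int,
        "gravity": bool,
        "settle_tol": "length",
        "capture_radius": "length",
        "log_level": str,
    },
}


def _parse_section(name: str, raw: dict) -> dict:
    schema = _SCHEMA[name]
    out = {}
    for key, value in raw.items():
        if key not in schema:
            raise UnknownKeyError(
                f"unknown config key {name}.{key!r}; known keys: {sorted(schema)}"
            )
        rule = schema[key]
        if isinstance(rule, str):
            out[key] = parse_quantity(value, rule, f"{name}.{key}")
        elif not isinstance(value, rule):
            raise ConfigError(
                f"config key {name}.{key!r} must be {rule.__name__}, got {value!r}"
            )
        else:
            out[key] = value
    return out


def load_config(path: str | Path) -> RunConfig:
    """Load, validate and unit-normalise a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    for section in raw:
        if section not in _SCHEMA:
            raise UnknownKeyError(
                f"unknown config section {section!r}; known: {sorted(_SCHEMA)}"
            )

    med = _parse_section("medium", raw.get("medium") or {})
    cav = _parse_section("cavity", raw.get("cavity") or {})
    par = _parse_section("particle", raw.get("particle") or {})
    run = _parse_section("run", raw.get("run") or {})

    medium = Medium(
        density=med.get("density", 1000.0),
        sound_speed=med.get("sound_speed", 1500.0),
        dynamic_viscosity=med.get("dynamic_viscosity", 1.0e-3),
        compressibility=med.get("compressibility"),
    )
    cavity = CavityConfig(
        height=cav.get("height", 0.0675),
        drive_frequency=cav.get("drive_frequency", 1.6e6),
        pressure_amplitude=cav.get("pressure_amplitude", 1.0e6),
        actuator_radius=cav.get("actuator_radius", 0.010),
        radial_envelope_width=cav.get("radial_envelope_width", 0.010),
        vessel_inner_radius=cav.get("vessel_inner_radius", 0.020),
    )
    particle = ParticleSpec(
        radius=par.get("diameter", 30e-6) / 2.0,
        density=par.get("density", 1050.0),
        compressibility=par.get("compressibility", CELL_COMPRESSIBILITY),
        rigid=par.get("rigid", False),
    )
    settings = RunSettings(
        duration=run.get("duration", 1.0),
        dt=run.get("dt", 1e-3),
        mode=run.get("mode", "overdamped"),
        seed=run.get("seed", 0),
        gravity=run.get("gravity", True),
        settle_tol=run.get("settle_tol", 5e-6),
        capture_radius=run.get("capture_radius", 60e-6),
        log_level=run.get("log_level", "INFO"),
    )
    return RunConfig(medium=medium, cavity=cavity, particle=particle, run=settings)
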