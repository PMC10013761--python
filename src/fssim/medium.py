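"""Fluid medium and resonator cavity descriptions.

The simulator works in cylindrical coordinates (r, z): z = 0 at the actuator
face, z increasing upward toward the reflector, gravity along -z.  All fields
are SI; helpers elsewhere convert from config-file units on load.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError


@dataclass(frozen=True)
class Medium:
    """A quiescent Newtonian fluid supporting the standing wave.

    Parameters
    ----------
    density : float
        Mass density rho_f in kg/m^3.
    sound_speed : float
        Speed of sound c in m/s.
    dynamic_viscosity : float
        Dynamic viscosity mu in Pa*s.
    compressibility : float, optional
        Isentropic compressibility kappa_f in 1/Pa.  If omitted it is set to
        1/(rho_f * c^2), the value consistent with the sound speed.
    """

    density: float = 1000.0
    sound_speed: float = 1500.0
    dynamic_viscosity: float = 1.0e-3
    compressibility: float | None = None

    def __post_init__(self) -> None:
        if self.density <= 0 or self.sound_speed <= 0 or self.dynamic_viscosity <= 0:
            raise InvalidParameterError(
                "medium density, sound speed and viscosity must be strictly positive"
            )
        if self.compressibility is None:
            object.__setattr__(
                self,
                "compressibility",
                1.0 / (self.density * self.sound_speed**2),
            )
        elif self.compressibility <= 0:
            raise InvalidParameterError("medium compressibility must be strictly positive")

    @classmethod
    def water(cls) -> "Medium":
        """Water at cell-culture conditions (rho = 1000 kg/m^3, c = 1500 m/s)."""
        return cls()


@dataclass(frozen=True)
class CavityConfig:
    """Geometry and drive of the actuator-reflector water column.

    The actuator is modelled as an effective pressure boundary with a radially
    decaying envelope; no piezoelectric physics is represented.

    Parameters
    ----------
    height : float
        Actuator-to-reflector distance L in m.
    drive_frequency : float
        Drive frequency f in Hz.
    pressure_amplitude : float
        Peak pressure amplitude p0 at the antinode on the axis, in Pa.  The
        drive amplitude of the physical device is not known; every
        amplitude-dependent output is conditional on this value.
    actuator_radius : float
        Radius of the actuator disc in m.
    radial_envelope_width : float
        Width sigma_r of the Gaussian radial envelope in m.
    vessel_inner_radius : float
        Inner radius of the cylindrical culture vessel in m.
    """

    height: float = 0.0675
    drive_frequency: float = 1.6e6
    pressure_amplitude: float = 1.0e6
    actuator_radius: float = 0.010
    radial_envelope_width: float = 0.010
    vessel_inner_radius: float = 0.020

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise InvalidParameterError("cavity height must be > 0")
        if self.drive_frequency <= 0:
            raise InvalidParameterError("drive frequency must be > 0")
        if self.pressure_amplitude < 0:
            raise InvalidParameterError("pressure amplitude must be >= 0")
        if not (0 < self.actuator_radius <= self.vessel_inner_radius):
            raise InvalidParameterError(
                "actuator radius must satisfy 0 < Ra <= vessel inner radius"
            )
        if self.radial_envelope_width <= 0:
            raise InvalidParameterError("radial envelope width must be > 0")
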