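"""Forces on a spherical particle in the standing wave.

The primary radiation force is the negative gradient of the Gor'kov potential
of a small compressible sphere, attenuated by a finite-size factor G(2ka)
(the volume average of the force density over the sphere) so the model keeps
a meaningful regime change when the diameter approaches the wavelength:

    U(r, z) = 2 pi a^3 Phi * E_ac(r) * cos(2 k z) * G(2 k a)

with the acoustic contrast factor Phi = f1/3 + f2/2 built from the monopole
coefficient f1 = 1 - kappa_p/kappa_f and dipole coefficient
f2 = 2 (rho_p - rho_f) / (2 rho_p + rho_f).  Particles with Phi > 0 collect
at pressure nodes.  Stokes drag and net buoyant weight close the dynamics;
Basset history, added mass and inter-particle forces are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, OutOfDomainError
from .field import StandingWaveField, energy_density
from .medium import Medium

__all__ = [
    "ParticleSpec",
    "ForceBreakdown",
    "contrast_factor",
    "finite_size_factor",
    "gorkov_potential",
    "radiation_force",
    "drag_force",
    "buoyant_weight",
    "trap_stiffness",
]

#: Literature-typical isentropic compressibility of a mammalian cell (1/Pa).
CELL_COMPRESSIBILITY = 4.0e-10


@dataclass(frozen=True)
class ParticleSpec:
    """A rigid or compressible sphere suspended in the medium.

    ``rigid`` = True reproduces the rigid-matter assumption used for the
    device model (compressibility treated as zero); the default keeps a
    cell-like finite compressibility.
    """

    radius: float = 15e-6
    density: float = 1050.0
    compressibility: float = CELL_COMPRESSIBILITY
    rigid: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidParameterError("particle radius must be > 0")
        if self.density <= 0:
            raise InvalidParameterError("particle density must be > 0")
        if self.compressibility < 0:
            raise InvalidParameterError("particle compressibility must be >= 0")

    @property
    def effective_compressibility(self) -> float:
        return 0.0 if self.rigid else self.compressibility

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def volume(self) -> float:
        return (4.0 / 3.0) * np.pi * self.radius**3

    def mass(self) -> float:
        return self.density * self.volume

    @classmethod
    def cell(cls) -> "ParticleSpec":
        """The 30-um, 1050 kg/m^3 single-cell model."""
        return cls(radius=15e-6, density=1050.0)

    @classmethod
    def aggregate(cls, diameter: float) -> "ParticleSpec":
        """A rigid spherical aggregate of the given diameter (1050 kg/m^3)."""
        return cls(radius=diameter / 2.0, density=1050.0, rigid=True)


@dataclass(frozen=True)
class ForceBreakdown:
    """Decomposition of the instantaneous force on a particle (N).

    ``total`` is the vector sum of all parts in (r, z) components.
    """

    axial_radiation: float
    radial_radiation: float
    drag: np.ndarray
    buoyant_weight: np.ndarray
    total: np.ndarray


def contrast_factor(particle: ParticleSpec, medium: Medium) -> float:
    """Acoustic contrast factor Phi = f1/3 + f2/2 (dimensionless)."""
    f1 = 1.0 - particle.effective_compressibility / medium.compressibility
    f2 = (
        2.0
        * (particle.density - medium.density)
        / (2.0 * particle.density + medium.density)
    )
    return f1 / 3.0 + f2 / 2.0


def finite_size_factor(x):
    """Finite-size attenuation G(x) = 3 (sin x - x cos x) / x^3, x = 2ka.

    G(0) = 1 by continuous extension (series used below x = 1e-2 to avoid
    cancellation); the first zero sits at x ~ 4.4934, past which the trap
    sign inverts.  This is the volume average of the point-force density
    over the sphere.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InvalidParameterError("finite-size argument x = 2ka must be >= 0")
    small = x < 1e-2
    xs = np.where(small, 1.0, x)  # avoid 0/0 in the closed form
    closed = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    series = 1.0 - x**2 / 10.0 + x**4 / 280.0
    out = np.where(small, series, closed)
    return out if out.ndim else float(out)


def gorkov_potential(
    particle: ParticleSpec,
    field: StandingWaveField,
    medium: Medium,
    r,
    z,
):
    """Time-averaged trapping potential U(r, z) in joules (vectorised)."""
    phi = contrast_factor(particle, medium)
    g_fs = finite_size_factor(2.0 * field.wavenumber * particle.radius)
    e_ac = energy_density(field, medium, r)
    return (
        2.0
        * np.pi
        * particle.radius**3
        * phi
        * e_ac
        * np.cos(2.0 * field.wavenumber * np.asarray(z, dtype=float))
        * g_fs
    )


def _check_inside(field: StandingWaveField, r, z) -> None:
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > field.height):
        raise OutOfDomainError("axial position outside the cavity [0, L]")
    if np.any(np.abs(r) > field.cavity.vessel_inner_radius):
        raise OutOfDomainError("radial position outside the vessel")


def radiation_force(
    particle: ParticleSpec,
    field: StandingWaveField,
    medium: Medium,
    position: tuple[float, float],
) -> ForceBreakdown:
    """Radiation-force components -grad U at ``position`` = (r, z).

    The axial part is 4 pi Phi k a^3 E_ac(r) sin(2kz) G(2ka); it vanishes at
    nodes and, for Phi > 0, points toward the nearest node from both flanks.
    The radial part follows from the analytic envelope gradient.
    """
    r, z = position
    _check_inside(field, r, z)
    k = field.wavenumber
    phi = contrast_factor(particle, medium)
    g_fs = finite_size_factor(2.0 * k * particle.radius)
    coeff = 2.0 * np.pi * particle.radius**3 * phi * g_fs

    e_ac = energy_density(field, medium, r)
    # dE_ac/dr = 2 E_ac0 E(r) E'(r); E_ac(r) = E_ac0 E(r)^2
    e_r = field.envelope(r)
    de_r = field.envelope.derivative(r)
    e_ac0 = field.pressure_amplitude**2 / (
        4.0 * medium.density * medium.sound_speed**2
    )
    de_ac = 2.0 * e_ac0 * e_r * de_r

    f_axial = 2.0 * k * coeff * e_ac * np.sin(2.0 * k * z)
    f_radial = -coeff * np.cos(2.0 * k * z) * de_ac

    zero = np.zeros(2)
    total = np.array([f_radial, f_axial])
    return ForceBreakdown(
        axial_radiation=float(f_axial),
        radial_radiation=float(f_radial),
        drag=zero,
        buoyant_weight=zero.copy(),
        total=total,
    )


def drag_force(particle: ParticleSpec, medium: Medium, velocity) -> np.ndarray:
    """Stokes drag -6 pi mu a v on a sphere in quiescent fluid (N)."""
    v = np.asarray(velocity, dtype=float)
    return -6.0 * np.pi * medium.dynamic_viscosity * particle.radius * v


def buoyant_weight(
    particle: ParticleSpec, medium: Medium, g: float = 9.81
) -> np.ndarray:
    """Net gravity (rho_p - rho_f) V g, directed along -z, as an (r, z) vector."""
    if g < 0:
        raise InvalidParameterError("gravitational acceleration must be >= 0")
    w = (particle.density - medium.density) * particle.volume * g
    return np.array([0.0, -w])


def total_force(
    particle: ParticleSpec,
    field: StandingWaveField,
    medium: Medium,
    position: tuple[float, float],
    velocity=(0.0, 0.0),
    g: float = 9.81,
    gravity_on: bool = True,
) -> ForceBreakdown:
    """Full force breakdown: radiation + Stokes drag + buoyant weight."""
    rad = radiation_force(particle, field, medium, position)
    drag = drag_force(particle, medium, velocity)
    weight = buoyant_weight(particle, medium, g) if gravity_on else np.zeros(2)
    total = (
        np.array([rad.radial_radiation, rad.axial_radiation]) + drag + weight
    )
    return ForceBreakdown(
        axial_radiation=rad.axial_radiation,
        radial_radiation=rad.radial_radiation,
        drag=drag,
        buoyant_weight=weight,
        total=total,
    )


def trap_stiffness(
    particle: ParticleSpec, field: StandingWaveField, medium: Medium, r=0.0
) -> float:
    """Axial restoring stiffness -dF_z/dz at a node: 8 pi Phi k^2 a^3 E_ac G (N/m)."""
    k = field.wavenumber
    phi = contrast_factor(particle, medium)
    g_fs = finite_size_factor(2.0 * k * particle.radius)
    e_ac = energy_density(field, medium, r)
    return 8.0 * np.pi * phi * k**2 * particle.radius**3 * e_ac * g_fs
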