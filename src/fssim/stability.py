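"""Size-dependent suspension stability and surface stress of aggregates.

The normative stability classifier is the wavelength rule: a spherical
aggregate is stably levitated at a node only if its diameter is strictly
smaller than the acoustic wavelength (937.5 um for water at 1.6 MHz), the
condition for the ultrasound pressures across the sphere to remain
unbalanced in the trapping sense.  A 1-s inertial trajectory from the
reference start point provides a dynamic displacement cross-check so that
amplitude assumptions cannot silently flip the headline sweep.

Surface stress is defined as the surface average over the sphere of the
absolute first-order pressure, with the carrier time factor |cos(omega t)|
averaged analytically to 2/pi (samples are asynchronous with the 1.6-MHz
carrier, so every sample sees the full-cycle average).  Absolute values are
proportional to the drive amplitude p0 and to this definition; only the
ordering across sizes is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, OutOfDomainError
from .field import StandingWaveField
from .forces import ParticleSpec
from .medium import Medium
from .tracer import Trajectory, trace

__all__ = [
    "StabilityRecord",
    "classify_stability",
    "sweep_stability",
    "surface_stress",
    "confinement_band",
]

#: Reference start point of the aggregate sweep: (r, z) = (2.5, 32.25) mm.
SWEEP_START = (2.5e-3, 32.25e-3)
#: Stress sampling cadence: every 2 ms over a 1-s window.
STRESS_SAMPLE_INTERVAL = 2e-3
STRESS_WINDOW = 1.0


@dataclass
class StabilityRecord:
    """Sweep output for one aggregate diameter.

    ``max_axial_displacement`` is the largest axial excursion from the start
    point over the window; ``max_node_distance`` is the largest distance to
    the nearest node along the way (staying below lambda/4 means the particle
    never left its trapping cell).
    """

    diameter: float
    max_axial_displacement: float
    max_node_distance: float
    stable: bool
    mean_surface_stress: float
    stress_samples: np.ndarray


def classify_stability(diameter: float, field: StandingWaveField) -> bool:
    """True iff the aggregate diameter is strictly below the wavelength."""
    if diameter <= 0:
        raise InvalidParameterError("diameter must be > 0")
    return diameter < field.wavelength


def _int_abs_cos(x):
    """Antiderivative F(x) = integral_0^x |cos s| ds, vectorised and odd."""
    x = np.asarray(x, dtype=float)
    sign = np.sign(x)
    ax = np.abs(x)
    n, rem = np.divmod(ax, np.pi)
    f = np.where(rem <= np.pi / 2.0, np.sin(rem), 2.0 - np.sin(rem))
    return sign * (2.0 * n + f)


def _mean_abs_cos(lo, hi):
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    span = hi - lo
    out = np.where(
        span == 0,
        np.abs(np.cos(lo)),
        (_int_abs_cos(hi) - _int_abs_cos(lo)) / np.where(span == 0, 1.0, span),
    )
    return out if out.ndim else float(out)


def surface_stress(
    diameter: float,
    position,
    field: StandingWaveField,
    medium: Medium,
    sample_interval: float = STRESS_SAMPLE_INTERVAL,
    window: float = STRESS_WINDOW,
) -> tuple[float, np.ndarray]:
    """Mean and per-sample surface-averaged |pressure| on a sphere (Pa).

    ``position`` is either a fixed (r, z) centre or a :class:`Trajectory`
    whose samples are interpolated at the stress sampling times.  Each sample
    is (2/pi) * p0 * E(r_c) * <|cos(k z_s)|> with the angled average taken
    analytically over the sphere surface (the surface measure is uniform in
    the axial coordinate of the sphere, so the average reduces to a 1-D
    integral over [z_c - a, z_c + a]).  The envelope is evaluated at the
    centre radius: it varies on the centimetre scale, three orders above the
    sphere radius.

    Raises :class:`OutOfDomainError` if the sphere ever extends outside the
    cavity.
    """
    if sample_interval <= 0 or window < sample_interval:
        raise InvalidParameterError("need sample_interval > 0 and window >= sample_interval")
    a = diameter / 2.0
    n_samples = int(np.floor(window / sample_interval)) + 1
    t_s = np.arange(n_samples) * sample_interval
    if isinstance(position, Trajectory):
        r_c = np.interp(t_s, position.t, position.r)
        z_c = np.interp(t_s, position.t, position.z)
    else:
        r_c = np.full(n_samples, float(position[0]))
        z_c = np.full(n_samples, float(position[1]))
    if np.any(z_c - a < 0) or np.any(z_c + a > field.height):
        raise OutOfDomainError("sphere extends outside the cavity during sampling")

    k = field.wavenumber
    factor = _mean_abs_cos(k * (z_c - a), k * (z_c + a))
    samples = (2.0 / np.pi) * field.pressure_amplitude * field.envelope(r_c) * factor
    return float(np.mean(samples)), samples


def sweep_stability(
    diameters,
    field: StandingWaveField,
    medium: Medium,
    spec_template: ParticleSpec | None = None,
    window: float = STRESS_WINDOW,
    start: tuple[float, float] = SWEEP_START,
    sample_interval: float = STRESS_SAMPLE_INTERVAL,
    mode: str = "inertial",
    g_on: bool = True,
) -> list[StabilityRecord]:
    """Run the aggregate-diameter sweep from the reference start point.

    For each diameter a ``window``-long trajectory (inertial by default, the
    appropriate regime for >= 200-um aggregates) is integrated from ``start``,
    the maximum axial excursion from the initial position is recorded, and
    the wavelength classifier plus the stress series are attached.
    """
    diameters = np.atleast_1d(np.asarray(diameters, dtype=float))
    if np.any(diameters <= 0):
        raise InvalidParameterError("diameters must be > 0")
    if np.any(diameters >= field.height):
        raise InvalidParameterError("aggregate diameter must be below the cavity height")
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    if not (0 <= start[1] <= field.height):
        raise InvalidParameterError("start position outside the cavity")

    if spec_template is None:
        spec_template = ParticleSpec.aggregate(diameters[0])
    specs = [
        ParticleSpec(
            radius=d / 2.0,
            density=spec_template.density,
            compressibility=spec_template.compressibility,
            rigid=spec_template.rigid,
        )
        for d in diameters
    ]
    positions = np.tile(np.asarray(start, dtype=float), (len(specs), 1))
    trajectories = trace(
        positions,
        specs,
        field,
        medium,
        duration=window,
        dt=sample_interval,
        mode=mode,
        g_on=g_on,
    )
    records = []
    for d, traj in zip(diameters, trajectories):
        mean_stress, samples = surface_stress(
            d, traj, field, medium, sample_interval, window
        )
        _, node_z = field.nearest_node(traj.z)
        records.append(
            StabilityRecord(
                diameter=float(d),
                max_axial_displacement=float(np.max(np.abs(traj.z - traj.z[0]))),
                max_node_distance=float(np.max(np.abs(traj.z - node_z))),
                stable=classify_stability(float(d), field),
                mean_surface_stress=mean_stress,
                stress_samples=samples,
            )
        )
    return records


def confinement_band(
    field: StandingWaveField, stress_threshold: float, r: float = 0.0
) -> float:
    """Axial half-thickness around a node where |p| stays below a threshold.

    Solves |p0 E(r) sin(k z~)| <= threshold for the distance z~ from a node:
    z~ = arcsin(min(1, thr / (p0 E(r)))) / k.  A threshold at or above the
    local amplitude opens the whole inter-node flank lambda/4.
    """
    if stress_threshold < 0:
        raise InvalidParameterError("stress threshold must be >= 0")
    p_local = field.pressure_amplitude * float(field.envelope(r))
    if p_local == 0.0:
        return field.wavelength / 4.0
    ratio = min(1.0, stress_threshold / p_local)
    return float(np.arcsin(ratio) / field.wavenumber)
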