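"""Trajectory integration, settling detection and node clustering.

Two regimes are supported.  In the overdamped mode the velocity is the
instantaneous force divided by the Stokes drag coefficient (appropriate for
single cells, whose momentum relaxation time rho_p d^2 / (18 mu) ~ 5e-5 s is
far below the trap time scale).  In the inertial mode the full momentum
equation m dv/dt = F - gamma v is integrated with a semi-implicit
(symplectic-Euler, drag-implicit) scheme, appropriate for aggregates of a few
hundred micrometres whose relaxation time approaches the observation window.

Both modes sub-step adaptively so that no sub-step moves a particle more than
lambda/20; trajectories are reported on a uniform output grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .errors import IntegrationInstabilityError, InvalidParameterError
from .field import StandingWaveField
from .forces import ParticleSpec, contrast_factor, finite_size_factor
from .medium import Medium

__all__ = [
    "ParticleState",
    "Trajectory",
    "trace",
    "settle_time",
    "cluster_by_node",
    "run_seeding",
]

#: Default settling tolerance: ~lambda/200 at the reference drive.
DEFAULT_SETTLE_TOL = 5e-6
#: Default cluster capture radius: two cell diameters.
DEFAULT_CAPTURE_RADIUS = 60e-6


@dataclass
class ParticleState:
    """Position/velocity snapshot of one particle."""

    id: int
    position: tuple[float, float]
    velocity: tuple[float, float] = (0.0, 0.0)
    settled: bool = False


@dataclass
class Trajectory:
    """One particle's sampled path on a uniform time grid starting at 0."""

    particle_id: int
    t: np.ndarray
    r: np.ndarray
    z: np.ndarray
    boundary_events: int = 0
    settle_time: float | None = None


class _FieldCoefficients:
    """Precomputed per-particle force coefficients for vectorised stepping."""

    def __init__(
        self,
        radii: np.ndarray,
        density: float,
        phi: np.ndarray,
        field: StandingWaveField,
        medium: Medium,
        g_on: bool,
        g: float,
    ):
        k = field.wavenumber
        g_fs = finite_size_factor(2.0 * k * radii)
        # U = C * E_ac(r) * cos(2kz);  F_z = 2 k C E_ac sin(2kz)
        self.C = 2.0 * np.pi * radii**3 * phi * g_fs
        self.k = k
        self.e_ac0 = field.pressure_amplitude**2 / (
            4.0 * medium.density * medium.sound_speed**2
        )
        self.envelope = field.envelope
        self.gamma = 6.0 * np.pi * medium.dynamic_viscosity * radii
        self.mass = density * (4.0 / 3.0) * np.pi * radii**3
        vol = (4.0 / 3.0) * np.pi * radii**3
        self.weight = (density - medium.density) * vol * g if g_on else np.zeros_like(radii)

    def force(self, r: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        e = self.envelope(r)
        de = self.envelope.derivative(r)
        e_ac = self.e_ac0 * e**2
        de_ac = 2.0 * self.e_ac0 * e * de
        two_kz = 2.0 * self.k * z
        f_z = 2.0 * self.k * self.C * e_ac * np.sin(two_kz) - self.weight
        f_r = -self.C * np.cos(two_kz) * de_ac
        return f_r, f_z


def _as_position_array(particles) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept ParticleState list or (n, 2) array; return ids, r0, z0."""
    if len(particles) and isinstance(particles[0], ParticleState):
        ids = np.array([p.id for p in particles])
        pos = np.array([p.position for p in particles], dtype=float)
    else:
        pos = np.atleast_2d(np.asarray(particles, dtype=float))
        ids = np.arange(pos.shape[0])
    return ids, pos[:, 0].copy(), pos[:, 1].copy()


def trace(
    particles,
    spec: ParticleSpec | Sequence[ParticleSpec],
    field: StandingWaveField,
    medium: Medium,
    duration: float,
    dt: float,
    mode: str = "overdamped",
    g_on: bool = True,
    g: float = 9.81,
    seed: int | None = None,
    max_substeps: int = 200_000,
) -> list[Trajectory]:
    """Integrate all particles and sample on a uniform grid of spacing ``dt``.

    ``particles`` is a list of :class:`ParticleState` or an (n, 2) array of
    initial (r, z) positions.  ``spec`` is a single :class:`ParticleSpec`
    shared by all particles or one per particle (sharing density).  The
    ``seed`` argument is accepted for interface symmetry; the deterministic
    dynamics consume no randomness.

    Raises :class:`IntegrationInstabilityError` if the displacement cap
    (lambda/20 per sub-step) cannot be honoured within ``max_substeps``
    sub-steps per output interval.
    """
    if duration <= 0 or dt <= 0 or dt > duration + 1e-15:
        raise InvalidParameterError("need 0 < dt <= duration")
    if mode not in ("overdamped", "inertial"):
        raise InvalidParameterError(f"unknown integration mode {mode!r}")

    ids, r, z = _as_position_array(particles)
    n = r.size
    if isinstance(spec, ParticleSpec):
        radii = np.full(n, spec.radius)
        phi = np.full(n, contrast_factor(spec, medium))
        density = spec.density
    else:
        radii = np.array([s.radius for s in spec], dtype=float)
        phi = np.array([contrast_factor(s, medium) for s in spec])
        density = spec[0].density

    coeff = _FieldCoefficients(radii, density, phi, field, medium, g_on, g)
    lam = field.wavelength
    disp_cap = lam / 20.0
    height = field.height
    r_max = field.cavity.vessel_inner_radius

    n_out = int(round(duration / dt))
    t_grid = np.arange(n_out + 1) * dt
    R = np.empty((n_out + 1, n))
    Z = np.empty((n_out + 1, n))
    R[0], Z[0] = r, z
    vr = np.zeros(n)
    vz = np.zeros(n)
    boundary_events = np.zeros(n, dtype=int)

    # Inertial stability cap: resolve the stiffest trap oscillation present.
    if mode == "inertial":
        kappa_max = np.max(4.0 * coeff.k**2 * np.abs(coeff.C) * coeff.e_ac0 / coeff.mass)
        dt_osc = 0.05 * 2.0 * np.pi / np.sqrt(kappa_max) if kappa_max > 0 else np.inf

    def clamp() -> None:
        low_z = z < 0.0
        high_z = z > height
        out_r = np.abs(r) > r_max
        if low_z.any() or high_z.any() or out_r.any():
            boundary_events[low_z | high_z | out_r] += 1
            np.clip(z, 0.0, height, out=z)
            np.clip(r, -r_max, r_max, out=r)
            vz[low_z | high_z] = 0.0
            vr[out_r] = 0.0

    for i_out in range(1, n_out + 1):
        remaining = dt
        steps = 0
        while remaining > 1e-18:
            steps += 1
            if steps > max_substeps:
                raise IntegrationInstabilityError(
                    "sub-step displacement cap could not be met within "
                    f"{max_substeps} sub-steps per output interval"
                )
            if mode == "overdamped":
                f_r, f_z = coeff.force(r, z)
                ur, uz = f_r / coeff.gamma, f_z / coeff.gamma
                vmax = np.max(np.hypot(ur, uz))
                h = remaining if vmax == 0 else min(remaining, disp_cap / vmax)
                # midpoint step on dx/dt = F(x)/gamma
                rm = r + 0.5 * h * ur
                zm = np.clip(z + 0.5 * h * uz, 0.0, height)
                f_r, f_z = coeff.force(rm, zm)
                vr, vz = f_r / coeff.gamma, f_z / coeff.gamma
                r += h * vr
                z += h * vz
            else:
                vmax = np.max(np.hypot(vr, vz))
                h = min(remaining, dt_osc)
                if vmax > 0:
                    h = min(h, disp_cap / vmax)
                f_r, f_z = coeff.force(r, z)
                damp = 1.0 + h * coeff.gamma / coeff.mass
                vr = (vr + h * f_r / coeff.mass) / damp
                vz = (vz + h * f_z / coeff.mass) / damp
                r += h * vr
                z += h * vz
            clamp()
            remaining -= h
        R[i_out], Z[i_out] = r, z

    return [
        Trajectory(
            particle_id=int(ids[j]),
            t=t_grid,
            r=R[:, j].copy(),
            z=Z[:, j].copy(),
            boundary_events=int(boundary_events[j]),
        )
        for j in range(n)
    ]


def settle_time(
    trajectory: Trajectory, nodes: np.ndarray, tol: float = DEFAULT_SETTLE_TOL
) -> float | None:
    """Earliest time after which the particle stays within ``tol`` of one node.

    The condition is a suffix condition: the particle must remain inside the
    tolerance band of a single node through the end of the trajectory.
    Returns None if the final sample is outside every band.
    """
    if tol <= 0:
        raise InvalidParameterError("settle tolerance must be > 0")
    nodes = np.asarray(nodes, dtype=float)
    d = np.abs(trajectory.z[:, None] - nodes[None, :])
    node_idx = np.argmin(d, axis=1)
    within = d[np.arange(d.shape[0]), node_idx] <= tol
    if not within[-1]:
        return None
    final_node = node_idx[-1]
    ok = within & (node_idx == final_node)
    # last index where the condition fails, settle starts just after
    bad = np.nonzero(~ok)[0]
    start = bad[-1] + 1 if bad.size else 0
    return float(trajectory.t[start])


@dataclass
class OccupancyReport:
    """Counts of settled particles per node and per positional cluster."""

    n_total: int
    n_unsettled: int
    per_node: dict = dc_field(default_factory=dict)
    clusters: list = dc_field(default_factory=list)  # (node_index, size)

    @property
    def n_settled(self) -> int:
        return self.n_total - self.n_unsettled


def cluster_by_node(
    final_states: Sequence[ParticleState],
    nodes: np.ndarray,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS,
) -> OccupancyReport:
    """Assign settled particles to nearest nodes and group them into clusters.

    Within one node, particles form a cluster by single linkage: any chain of
    pairwise (r, z) distances below ``capture_radius`` joins one cluster.
    Aggregation here is positional bookkeeping only, no adhesion mechanics.
    """
    if capture_radius <= 0:
        raise InvalidParameterError("capture radius must be > 0")
    nodes = np.asarray(nodes, dtype=float)
    report = OccupancyReport(n_total=len(final_states), n_unsettled=0)
    settled = [s for s in final_states if s.settled]
    report.n_unsettled = len(final_states) - len(settled)
    if not settled:
        return report

    pos = np.array([s.position for s in settled], dtype=float)
    node_idx = np.argmin(np.abs(pos[:, 1][:, None] - nodes[None, :]), axis=1)
    for ni in np.unique(node_idx):
        sel = node_idx == ni
        report.per_node[int(ni)] = int(sel.sum())
        pts = pos[sel]
        labels = _single_linkage(pts, capture_radius)
        for lab in np.unique(labels):
            report.clusters.append((int(ni), int(np.sum(labels == lab))))
    return report


def _single_linkage(points: np.ndarray, threshold: float) -> np.ndarray:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree

    m = points.shape[0]
    if m == 1:
        return np.zeros(1, dtype=int)
    tree = cKDTree(points)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def run_seeding(
    n_particles: int,
    cavity,
    medium: Medium,
    spec: ParticleSpec,
    duration: float,
    seed: int,
    dt: float = 1e-3,
    mode: str = "overdamped",
    g_on: bool = True,
    settle_tol: float = DEFAULT_SETTLE_TOL,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS,
    field: StandingWaveField | None = None,
) -> dict:
    """Seed a uniform random suspension, trace it, and report node occupancy.

    The single integer ``seed`` governs all stochastic draws (initial
    positions; the dynamics itself is deterministic).  Reports are
    bit-identical across reruns with the same inputs.
    """
    from .field import build_field
    from .synthetic import generate_suspension

    if n_particles < 1:
        raise InvalidParameterError("need at least one particle")
    if field is None:
        field = build_field(cavity, medium)
    suspension = generate_suspension(n_particles, cavity, seed)
    trajectories = trace(
        suspension.positions, spec, field, medium, duration, dt, mode=mode, g_on=g_on
    )
    nodes = field.node_positions
    settle_times = []
    states = []
    for traj in trajectories:
        ts = settle_time(traj, nodes, settle_tol)
        traj.settle_time = ts
        if ts is not None:
            settle_times.append(ts)
        states.append(
            ParticleState(
                id=traj.particle_id,
                position=(traj.r[-1], traj.z[-1]),
                settled=ts is not None,
            )
        )
    occupancy = cluster_by_node(states, nodes, capture_radius)
    return {
        "n_particles": n_particles,
        "seed": seed,
        "fraction_settled": occupancy.n_settled / n_particles,
        "median_settle_time_s": float(np.median(settle_times)) if settle_times else None,
        "per_node_counts": {str(k): v for k, v in sorted(occupancy.per_node.items())},
        "n_clusters": len(occupancy.clusters),
        "n_unsettled": occupancy.n_unsettled,
    }
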