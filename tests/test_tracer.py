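"""Trajectory integration, settling detection, clustering and seeding runs."""

import numpy as np
import pytest

from fssim import (
    CavityConfig,
    ParticleSpec,
    ParticleState,
    Trajectory,
    build_field,
    cluster_by_node,
    contrast_factor,
    energy_density,
    gorkov_potential,
    run_seeding,
    settle_time,
    trace,
)
from fssim.errors import InvalidParameterError


def overdamped_tau(field, water, cell):
    """Closed-form linearised trap relaxation time 3 mu / (4 Phi k^2 a^2 E_ac)."""
    phi = contrast_factor(cell, water)
    e_ac = energy_density(field, water, 0.0)
    return (
        3.0
        * water.dynamic_viscosity
        / (4.0 * phi * field.wavenumber**2 * cell.radius**2 * e_ac)
    )


class TestOverdampedTrap:
    def test_particle_at_node_is_a_fixed_point(self, field, water, cell, mid_node):
        trajs = trace(
            [(0.0, mid_node)], cell, field, water, 0.02, 1e-3,
            mode="overdamped", g_on=False,
        )
        assert np.allclose(trajs[0].z, mid_node, atol=1e-15)

    def test_linearised_decay_matches_closed_form_tau(self, field, water, cell, mid_node):
        """Near a node the numeric relaxation time agrees with
        tau = 3 mu / (4 Phi k^2 a^2 E_ac) ~ 13.5 ms to within 1%."""
        tau = overdamped_tau(field, water, cell)
        assert tau == pytest.approx(13.5e-3, rel=5e-3)
        z0 = mid_node + field.wavelength / 400
        trajs = trace(
            [(0.0, z0)], cell, field, water, 2 * tau, 1e-4,
            mode="overdamped", g_on=False,
        )
        ztil = trajs[0].z - mid_node
        slope = np.polyfit(trajs[0].t, np.log(ztil), 1)[0]
        assert -1.0 / slope == pytest.approx(tau, rel=1e-2)

    def test_travel_time_from_quarter_flank_matches_quadrature(
        self, field, water, cell, mid_node
    ):
        """Start at lambda/8 above a node; time to |z~| <= 5 um equals the
        closed-form quadrature T = ln(tan k z0 / tan k zf) / (2 k v0) ~ 46 ms."""
        k = field.wavenumber
        phi = contrast_factor(cell, water)
        e_ac = energy_density(field, water, 0.0)
        from fssim.forces import finite_size_factor

        g_fs = finite_size_factor(2 * k * cell.radius)
        v0 = 2.0 * phi * k * cell.radius**2 * e_ac * g_fs / (
            3.0 * water.dynamic_viscosity
        )
        z0, zf = field.wavelength / 8, 5e-6
        t_expected = np.log(np.tan(k * z0) / np.tan(k * zf)) / (2 * k * v0)
        trajs = trace(
            [(0.0, mid_node + z0)], cell, field, water, 0.1, 1e-4,
            mode="overdamped", g_on=False,
        )
        reached = np.nonzero(np.abs(trajs[0].z - mid_node) <= zf)[0][0]
        assert trajs[0].t[reached] == pytest.approx(t_expected, rel=0.02)
        assert t_expected == pytest.approx(0.046, rel=0.02)

    def test_potential_is_nonincreasing_along_trajectory(self, field, water, cell, mid_node):
        trajs = trace(
            [(2e-3, mid_node + field.wavelength / 8)], cell, field, water,
            0.05, 5e-4, mode="overdamped", g_on=False,
        )
        u = gorkov_potential(cell, field, water, trajs[0].r, trajs[0].z)
        assert np.all(np.diff(u) <= 1e-25)

    def test_overdamped_and_inertial_agree_for_single_cell(
        self, field, water, cell, mid_node
    ):
        """Momentum relaxation (~5e-5 s) is far below the trap time, so both
        integration modes land the 30-um cell on the same final position."""
        start = [(1e-3, mid_node + field.wavelength / 8)]
        kw = dict(duration=0.12, dt=1e-3, g_on=False)
        z_over = trace(start, cell, field, water, mode="overdamped", **kw)[0].z[-1]
        z_iner = trace(start, cell, field, water, mode="inertial", **kw)[0].z[-1]
        assert z_over == pytest.approx(z_iner, abs=1e-6)
        assert z_over == pytest.approx(mid_node, abs=2e-6)


class TestSettleTime:
    def test_constant_at_node_settles_at_zero(self, field):
        t = np.linspace(0, 1, 11)
        node = field.node_positions[5]
        traj = Trajectory(0, t, np.zeros(11), np.full(11, node))
        assert settle_time(traj, field.node_positions) == 0.0

    def test_enter_then_leave_band_is_unsettled(self, field):
        node = field.node_positions[5]
        t = np.linspace(0, 1, 5)
        z = np.array([node + 1e-4, node, node, node + 1e-4, node + 1e-4])
        assert settle_time(traj := Trajectory(0, t, np.zeros(5), z),
                           field.node_positions, tol=5e-6) is None

    def test_suffix_condition_picks_earliest_stable_time(self, field):
        node = field.node_positions[5]
        t = np.linspace(0, 1, 5)
        z = np.array([node + 1e-4, node + 2e-6, node, node, node])
        assert settle_time(Trajectory(0, t, np.zeros(5), z),
                           field.node_positions, tol=5e-6) == pytest.approx(0.25)

    def test_settle_time_scales_inversely_with_amplitude_squared(self, water, cell):
        """tau ~ 1/p0^2: doubling p0 quarters the time to reach the tolerance
        band from a fixed linear-regime start (within 5%)."""
        times = {}
        for p0 in (0.5e6, 1.0e6, 2.0e6):
            f = build_field(CavityConfig(pressure_amplitude=p0), water)
            node = f.node_positions[68]
            trajs = trace(
                [(0.0, node + f.wavelength / 100)], cell, f, water,
                0.5, 1e-4, mode="overdamped", g_on=False,
            )
            times[p0] = settle_time(trajs[0], f.node_positions, tol=2e-6)
        assert times[0.5e6] / times[1.0e6] == pytest.approx(4.0, rel=0.05)
        assert times[1.0e6] / times[2.0e6] == pytest.approx(4.0, rel=0.05)


class TestClustering:
    def test_single_cluster_at_one_node(self, field):
        node = field.node_positions[3]
        states = [
            ParticleState(i, (i * 1e-5, node + 1e-6), settled=True) for i in range(5)
        ]
        rep = cluster_by_node(states, field.node_positions, capture_radius=60e-6)
        assert rep.per_node == {3: 5}
        assert rep.clusters == [(3, 5)]

    def test_two_groups_at_adjacent_nodes(self, field):
        za, zb = field.node_positions[3], field.node_positions[4]
        states = [ParticleState(i, (0.0, za), settled=True) for i in range(3)] + [
            ParticleState(3 + i, (0.0, zb), settled=True) for i in range(2)
        ]
        rep = cluster_by_node(states, field.node_positions, capture_radius=60e-6)
        assert rep.per_node == {3: 3, 4: 2}
        assert sorted(rep.clusters) == [(3, 3), (4, 2)]

    def test_radial_separation_splits_clusters_within_a_node(self, field):
        node = field.node_positions[3]
        states = [ParticleState(0, (0.0, node), settled=True),
                  ParticleState(1, (1e-3, node), settled=True)]
        rep = cluster_by_node(states, field.node_positions, capture_radius=60e-6)
        assert rep.per_node == {3: 2}
        assert sorted(rep.clusters) == [(3, 1), (3, 1)]

    def test_particle_count_is_conserved(self, field):
        states = [
            ParticleState(i, (0.0, field.node_positions[i % 4]), settled=i % 3 != 0)
            for i in range(20)
        ]
        rep = cluster_by_node(states, field.node_positions)
        assert rep.n_unsettled + sum(rep.per_node.values()) == 20
        assert sum(size for _, size in rep.clusters) == rep.n_settled


@pytest.fixture(scope="module")
def strong_cavity():
    # Amplitude chosen so the worst-case trap time (vessel edge, where the
    # envelope is e^-2) stays well below a tenth of the 0.5-s window:
    # tau scales as 1/(p0 E(r))^2.
    return CavityConfig(pressure_amplitude=6.0e6)


class TestRunSeeding:
    def test_report_is_deterministic(self, strong_cavity, water, cell):
        kw = dict(duration=0.3, seed=11, dt=2e-3)
        rep1 = run_seeding(40, strong_cavity, water, cell, **kw)
        rep2 = run_seeding(40, strong_cavity, water, cell, **kw)
        assert rep1 == rep2

    def test_counts_conserved_and_high_settled_fraction(self, strong_cavity, water, cell):
        rep = run_seeding(200, strong_cavity, water, cell, duration=0.5, seed=3, dt=2e-3)
        assert sum(rep["per_node_counts"].values()) + rep["n_unsettled"] == 200
        assert rep["fraction_settled"] >= 0.99
        assert rep["median_settle_time_s"] < 0.25

    def test_rejects_empty_run(self, strong_cavity, water, cell):
        with pytest.raises(InvalidParameterError):
            run_seeding(0, strong_cavity, water, cell, duration=0.1, seed=1)


class TestTraceValidation:
    def test_rejects_bad_time_arguments(self, field, water, cell):
        with pytest.raises(InvalidParameterError):
            trace([(0.0, 1e-3)], cell, field, water, duration=0.0, dt=1e-3)
        with pytest.raises(InvalidParameterError):
            trace([(0.0, 1e-3)], cell, field, water, duration=0.1, dt=0.2)

    def test_rejects_unknown_mode(self, field, water, cell):
        with pytest.raises(InvalidParameterError):
            trace([(0.0, 1e-3)], cell, field, water, 0.1, 1e-3, mode="ballistic")

    def test_boundary_clamp_is_recorded(self, water):
        # dense particle, no field: it sinks and is clamped at the actuator
        f = build_field(CavityConfig(pressure_amplitude=0.0, height=1e-3), water)
        heavy = ParticleSpec(radius=100e-6, density=2000.0)
        trajs = trace([(0.0, 5e-4)], heavy, f, water, 2.0, 0.05, mode="overdamped")
        assert trajs[0].boundary_events > 0
        assert trajs[0].z[-1] == 0.0
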