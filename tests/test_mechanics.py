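"""Unit tests for the agent-based shell simulator."""

import math

import numpy as np
import pytest

from organoidyn import (
    DivisionSchedule,
    GeometryError,
    IntegrationError,
    OrganoidState,
    SimulationParams,
    compute_forces,
    divide_cells,
    initialize_sphere,
    simulate,
    step,
    update_lumen,
)
from organoidyn.mechanics import radius_for_count, rupture_pressure_scale


class TestInitialisation:
    def test_four_cells_form_a_tetrahedron(self):
        state = initialize_sphere(4, 10.0, SimulationParams())
        assert len(state.neighbour_edges) == 6
        degrees = np.zeros(4, int)
        for a, b in state.neighbour_edges:
            degrees[[a, b]] += 1
        assert (degrees == 3).all()

    def test_cells_sit_exactly_on_the_requested_sphere(self):
        state = initialize_sphere(100, 50.0, SimulationParams())
        radii = np.linalg.norm(state.positions - state.centre, axis=1)
        assert np.abs(radii - 50.0).max() < 1e-6

    def test_same_seed_reproduces_the_lattice_bit_exactly(self):
        params = SimulationParams(seed=7)
        a = initialize_sphere(100, 50.0, params, jitter=0.0)
        b = initialize_sphere(100, 50.0, params, jitter=0.0)
        assert a.mean_neighbour_distance() == b.mean_neighbour_distance()
        assert (a.positions == b.positions).all()

    def test_fewer_than_four_cells_is_rejected(self):
        with pytest.raises(GeometryError):
            initialize_sphere(3, 10.0, SimulationParams())

    def test_initial_pressure_is_the_configured_fraction(self):
        params = SimulationParams(start_pressure_fraction=0.1)
        state = initialize_sphere(64, 26.0, params)
        expected = 0.1 * rupture_pressure_scale(64, 26.0, params)
        assert state.pressure(params) == pytest.approx(expected, rel=1e-12)
        assert state.v_lumen == pytest.approx((4 / 3) * math.pi * 26.0**3)


class TestForces:
    def test_two_cells_at_rest_length_feel_nothing(self):
        state = OrganoidState(
            time=0.0,
            positions=np.array([[0.0, 0, 0], [10.0, 0, 0]]),
            radii=np.array([5.0, 5.0]),
            n=0.0,
            v_lumen=1.0,
            sealed=True,
            neighbour_edges={(0, 1)},
        )
        params = SimulationParams(ell0=10.0, k_bend=0.0)
        assert np.abs(compute_forces(state, params)).max() == 0.0

    def test_symmetric_shell_feels_purely_radial_pressure(
        self, octahedron_state, octahedron_params
    ):
        # springs at rest, zero bending deviation: force is P * a_i outward
        octahedron_state.n = 50.0
        forces = compute_forces(octahedron_state, octahedron_params)
        pressure = octahedron_state.pressure(octahedron_params)
        r_fit = octahedron_state.r_fit
        area_share = 4.0 * math.pi * r_fit**2 / 6
        rhat = octahedron_state.positions / np.linalg.norm(
            octahedron_state.positions, axis=1, keepdims=True
        )
        expected = pressure * area_share * rhat
        assert np.allclose(forces, expected, rtol=1e-12, atol=1e-12)

    def test_pressure_term_is_linear_in_substance_amount(
        self, octahedron_state, octahedron_params
    ):
        octahedron_state.n = 10.0
        f1 = compute_forces(octahedron_state, octahedron_params)
        octahedron_state.n = 20.0
        f2 = compute_forces(octahedron_state, octahedron_params)
        assert np.allclose(f2, 2.0 * f1, rtol=1e-12)

    def test_spring_forces_obey_newtons_third_law(self, rng):
        params = SimulationParams(k_bend=0.0)
        state = initialize_sphere(80, 25.0, params, rng=rng, jitter=2.0)
        state.n = 0.0  # isolate the spring part
        total = compute_forces(state, params).sum(axis=0)
        assert np.linalg.norm(total) < 1e-8 * params.k_spring * params.ell0


class TestLumen:
    def test_sealed_influx_is_exact_bookkeeping(self):
        params = SimulationParams(j_in=1.0)
        state = initialize_sphere(10, 8.0, params)  # mean edge far below rupture
        n_before = state.n
        update_lumen(state, params, 0.5)
        assert state.sealed
        assert state.n - n_before == pytest.approx(5.0, abs=1e-12)

    def test_substance_never_goes_negative_while_leaking(self):
        params = SimulationParams(j_in=0.0, j_out=10.0)
        state = initialize_sphere(10, 8.0, params)
        state.sealed = False
        state.n = 1.0
        update_lumen(state, params, 0.5)
        assert state.n == 0.0

    def test_overstretched_shell_ruptures_in_one_call(self):
        params = SimulationParams(j_in=0.0)
        # inflate a resting lattice so the mean edge is 1.01 * rupture threshold
        state = initialize_sphere(64, radius_for_count(64, params.ell0), params)
        factor = 1.01 * params.ell_rupture / state.mean_neighbour_distance()
        state.positions = state.positions * factor
        assert state.sealed
        update_lumen(state, params, 0.01)
        assert not state.sealed
        assert state.ruptured_last_step

    def test_relaxed_shell_reseals(self):
        params = SimulationParams(j_in=0.0)
        state = initialize_sphere(64, radius_for_count(64, params.ell0), params)
        state.sealed = False
        assert state.mean_neighbour_distance() < params.ell_seal
        update_lumen(state, params, 0.01)
        assert state.sealed


class TestDivision:
    def test_table_schedule_hits_the_target_count_exactly(self, rng):
        # the experimentally observed small organoid: 8 -> 107 cells in 144 h
        schedule = DivisionSchedule(mode="table", table=[(0.0, 8.0), (144.0, 107.0)])
        params = SimulationParams()
        state = initialize_sphere(8, radius_for_count(8, params.ell0), params)
        for t in np.arange(1.0, 144.5, 1.0):
            divide_cells(state, schedule, float(t), rng, dt=1.0)
            state.time = float(t)
        assert state.n_cells == 107

    def test_zero_rate_changes_nothing(self, rng):
        schedule = DivisionSchedule(mode="linear", slope=0.0)
        params = SimulationParams()
        state = initialize_sphere(16, 12.0, params)
        before = state.positions.copy()
        divide_cells(state, schedule, 1.0, rng, dt=1.0)
        assert state.n_cells == 16
        assert (state.positions == before).all()

    def test_deterministic_exponential_growth_matches_closed_form(self, rng):
        rate, dt = 0.05, 0.1
        schedule = DivisionSchedule(mode="exponential", rate=rate, deterministic=True)
        params = SimulationParams()
        state = initialize_sphere(16, 12.0, params)
        t = 0.0
        for _ in range(600):
            t += dt
            divide_cells(state, schedule, t, rng, dt=dt)
            state.time = t
        assert abs(state.n_cells - math.floor(16 * math.exp(rate * t))) <= 1

    def test_daughters_keep_the_parent_radius(self, rng):
        schedule = DivisionSchedule(mode="linear", slope=1000.0)
        params = SimulationParams()
        state = initialize_sphere(16, 12.0, params)
        divide_cells(state, schedule, 0.01, rng, dt=0.01)
        assert state.n_cells > 16
        assert (state.radii == state.radii[0]).all()


class TestStep:
    def test_resting_shell_is_a_fixed_point(
        self, octahedron_state, octahedron_params
    ):
        schedule = DivisionSchedule(mode="linear", slope=0.0)
        rng = np.random.default_rng(0)
        before = octahedron_state.positions.copy()
        for _ in range(10):
            step(octahedron_state, octahedron_params, schedule, rng)
        assert np.abs(octahedron_state.positions - before).max() < 1e-9

    def test_same_seed_gives_bit_identical_trajectories(self):
        schedule = DivisionSchedule(mode="linear", slope=0.5)
        params = SimulationParams(dt=0.02, seed=3, sigma=0.05)
        a = simulate(params, schedule, 2.0, n0=16)
        b = simulate(params, schedule, 2.0, n0=16)
        assert (a.v_lumen == b.v_lumen).all()
        assert (a.n_cells == b.n_cells).all()
        assert (a.n_substance == b.n_substance).all()

    def test_position_increment_decomposes_into_drift_plus_noise(self):
        params = SimulationParams(sigma=0.2, dt=0.01)
        schedule = DivisionSchedule(mode="linear", slope=0.0)
        state = initialize_sphere(32, radius_for_count(32, params.ell0), params)
        rng = np.random.default_rng(11)
        state.rebuild_edges()
        forces = compute_forces(state, params)
        before = state.positions.copy()
        step(state, params, schedule, rng)
        drifted = before + forces / params.gamma * params.dt
        expected = drifted + params.sigma * math.sqrt(params.dt) * state.last_noise
        assert np.array_equal(state.positions, expected)

    def test_non_finite_forces_raise_a_named_blowup_error(self):
        params = SimulationParams(sigma=0.0)
        schedule = DivisionSchedule(mode="linear", slope=0.0)
        state = initialize_sphere(16, 12.0, params)
        state.n = np.inf  # infinite pressure -> non-finite pressure force
        with pytest.raises(IntegrationError, match="cell"):
            step(state, params, schedule, np.random.default_rng(0))


class TestSimulate:
    def test_closed_lumen_without_influx_keeps_its_volume(self):
        params = SimulationParams(j_in=0.0, sigma=0.0, dt=0.02)
        schedule = DivisionSchedule(mode="linear", slope=0.0)
        traj = simulate(params, schedule, 10.0, n0=64, record_every=20)
        assert traj.n_ruptures == 0
        # after the initial mechanical equilibration the volume is static
        tail = traj.v_lumen[len(traj.v_lumen) // 2 :]
        assert np.ptp(tail) / tail.mean() < 0.01

    def test_small_organoid_under_linear_division_oscillates(self):
        params = SimulationParams(dt=0.02, seed=1)
        schedule = DivisionSchedule(mode="linear", slope=0.65)
        traj = simulate(params, schedule, 40.0, n0=9, record_every=20)
        assert traj.n_ruptures >= 1
        # deflation: the fitted radius drops after the first rupture
        first = np.searchsorted(traj.time, traj.rupture_times[0])
        after = traj.r_fit[first : first + 100]
        assert after.min() < traj.r_fit[first] * 0.98

    def test_recorded_pressure_obeys_the_gas_law_exactly(self):
        params = SimulationParams(dt=0.02, seed=2)
        schedule = DivisionSchedule(mode="linear", slope=0.2)
        traj = simulate(params, schedule, 5.0, n0=32)
        assert np.array_equal(
            traj.pressure, params.kappa * traj.n_substance / traj.v_lumen
        )

    def test_deterministic_trajectories_converge_at_first_order(self):
        # explicit Euler on the drift: halving dt should halve the error.
        # adjacency is frozen after initialisation because edge flips are
        # discrete events that would mask the smooth convergence order
        schedule = DivisionSchedule(mode="linear", slope=0.0)

        def final_radius(dt):
            params = SimulationParams(sigma=0.0, dt=dt, rebuild_every=10**9)
            traj = simulate(params, schedule, 2.0, n0=32, record_every=10**6)
            return traj.r_fit[-1]

        reference = final_radius(0.0025)
        errors = [abs(final_radius(dt) - reference) for dt in (0.04, 0.02, 0.01)]
        orders = [math.log2(errors[i] / errors[i + 1]) for i in range(2)]
        assert min(orders) >= 0.9


class TestValidation:
    def test_timestep_stability_bound_is_enforced(self):
        with pytest.raises(ValueError, match="stability"):
            SimulationParams(dt=1.0, k_spring=1.0, gamma=1.0)

    def test_seal_threshold_must_be_below_rupture_threshold(self):
        with pytest.raises(ValueError, match="ell_seal"):
            SimulationParams(ell_seal=14.0, ell_rupture=13.0)

    def test_table_counts_must_be_non_decreasing(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            DivisionSchedule(mode="table", table=[(0.0, 10.0), (10.0, 5.0)])
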