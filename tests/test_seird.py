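"""SEIRD reaction-diffusion model: initial conditions, semi-discrete residual,
BDF2 stepping against a stiff ODE oracle, and population conservation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from amrdmd.mesh import FEField, assemble_mass, build_interval_mesh, integrate
from amrdmd.seird import (
    BCSpec,
    NewtonError,
    Schedule,
    SEIRDParams,
    SEIRDSolver,
    SEIRDState,
    initial_conditions_1d,
    reaction_rates,
    seird_1d_params,
    semidiscrete_residual,
    total_population,
)

ALL_NEUMANN = BCSpec({"left": "neumann", "right": "neumann"})


def uniform_state(mesh, s, e, i=0.0, r=0.0, d=0.0, t=0.0):
    n = mesh.n_nodes
    return SEIRDState(
        t, mesh, np.full(n, s), np.full(n, e), np.full(n, i),
        np.full(n, r), np.full(n, d), np.zeros(n),
    )


def wellmixed_oracle(params, y0, t_eval):
    """High-accuracy stiff ODE solution of the spatially homogeneous system."""
    p = params.at(0.0)

    def rhs(t, y):
        f = reaction_rates(p, *[np.array([v]) for v in y])
        return [f[c][0] for c in ("s", "e", "i", "r", "d")]

    sol = solve_ivp(rhs, [t_eval[0], t_eval[-1]], y0, t_eval=t_eval,
                    rtol=1e-12, atol=1e-14, method="LSODA")
    return sol.y.T


def run_fem_wellmixed(mesh, params, y0, dt, n_steps):
    state = uniform_state(mesh, *y0)
    solver = SEIRDSolver(mesh, params, ALL_NEUMANN)
    prev, cur = None, state
    rows = [[cur.s[0], cur.e[0], cur.i[0], cur.r[0], cur.d[0]]]
    for _ in range(n_steps):
        new = solver.step(cur, prev, dt)
        prev, cur = cur, new
        rows.append([new.s[0], new.e[0], new.i[0], new.r[0], new.d[0]])
    return np.asarray(rows), cur


class TestInitialConditions:
    def test_peak_term_at_center(self):
        mesh = build_interval_mesh(0.0, 1.0, 100)  # node exactly at x = 0.35
        state = initial_conditions_1d(mesh)
        k = np.argmin(np.abs(mesh.node_coords - 0.35))
        # the Gaussian bump contributes exactly exp(0) = 1 at its centre,
        # on top of the small background and cluster tails
        assert state.s[k] >= 1.0
        x = 0.35
        tails = (
            np.exp(-((x + 1) ** 4))
            + 0.125 * (np.exp(-((x - 0.62) ** 4) / 1e-5)
                       + np.exp(-((x - 0.52) ** 4) / 1e-5)
                       + np.exp(-((x - 0.42) ** 4) / 1e-5))
            + 0.25 * np.exp(-((x - 0.735) ** 4) / 1e-5)
        )
        assert state.s[k] == pytest.approx(1.0 + tails, abs=1e-12)

    def test_exposed_center_value(self):
        mesh = build_interval_mesh(0.0, 1.0, 100)  # node exactly at x = 0.75
        state = initial_conditions_1d(mesh)
        k = np.argmin(np.abs(mesh.node_coords - 0.75))
        assert state.e[k] == pytest.approx(1.0 / 20.0, abs=1e-12)

    def test_full_nodal_vectors_match_formula(self):
        mesh = build_interval_mesh(0.0, 1.0, 500)
        state = initial_conditions_1d(mesh)
        x = mesh.node_coords
        s_ref = (
            np.exp(-((x + 1) ** 4))
            + np.exp(-((x - 0.35) ** 2) / 1e-2)
            + 0.125 * (np.exp(-((x - 0.62) ** 4) / 1e-5)
                       + np.exp(-((x - 0.52) ** 4) / 1e-5)
                       + np.exp(-((x - 0.42) ** 4) / 1e-5))
            + 0.25 * np.exp(-((x - 0.735) ** 4) / 1e-5)
        )
        np.testing.assert_allclose(state.s, s_ref, atol=1e-14)
        np.testing.assert_allclose(state.e, np.exp(-((x - 0.75) ** 4) / 1e-5) / 20.0,
                                   atol=1e-14)
        for name in ("i", "r", "d", "c"):
            assert np.all(getattr(state, name) == 0.0)

    def test_wrong_domain_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            initial_conditions_1d(build_interval_mesh(0.0, 2.0, 10))


class TestResidual:
    def test_susceptible_only_steady_state(self):
        mesh = build_interval_mesh(0.0, 1.0, 20)
        p = SEIRDParams(alpha=0.1, beta_i=0.4, beta_e=0.4, delta=0.01,
                        gamma_i=0.05, gamma_e=0.1)  # all diffusion zero
        state = uniform_state(mesh, s=0.7, e=0.0)
        res = semidiscrete_residual(state, p)
        for comp in ("s", "e", "i", "r", "d"):
            np.testing.assert_allclose(res[comp], 0.0, atol=1e-14)

    def test_zero_mortality_makes_deceased_residual_pure_mass(self, rng):
        mesh = build_interval_mesh(0.0, 1.0, 15)
        p = SEIRDParams(alpha=0.1, beta_i=0.4, beta_e=0.4, delta=0.0,
                        gamma_i=0.05, gamma_e=0.1)
        n = mesh.n_nodes
        state = SEIRDState(0.0, mesh, rng.uniform(0.1, 1, n), rng.uniform(0, 0.2, n),
                           rng.uniform(0, 0.2, n), np.zeros(n), np.zeros(n), np.zeros(n))
        dudt = {c: rng.normal(size=n) for c in ("s", "e", "i", "r", "d")}
        res = semidiscrete_residual(state, p, dudt=dudt)
        M = assemble_mass(mesh)
        np.testing.assert_allclose(res["d"], M @ dudt["d"], atol=1e-13)

    def test_uniform_state_reduces_to_ode_rhs_times_row_sums(self):
        mesh = build_interval_mesh(0.0, 1.0, 25)
        p = seird_1d_params()
        state = uniform_state(mesh, s=0.4, e=0.02, i=0.01)
        res = semidiscrete_residual(state, p)
        M = assemble_mass(mesh)
        row_sums = np.asarray(M.sum(axis=1)).ravel()
        f = reaction_rates(p.at(0.0), state.s, state.e, state.i, state.r, state.d)
        for comp in ("s", "e", "i", "r", "d"):
            np.testing.assert_allclose(res[comp], -row_sums * f[comp], atol=1e-10)

    def test_dirichlet_rows_become_constraints(self):
        mesh = build_interval_mesh(0.0, 1.0, 10)
        state = uniform_state(mesh, s=0.5, e=0.1)
        res = semidiscrete_residual(state, seird_1d_params(),
                                    BCSpec({"right": "dirichlet0"}))
        assert res["s"][-1] == pytest.approx(0.5)  # u - 0 at the boundary node

    def test_allee_requires_positive_population(self):
        mesh = build_interval_mesh(0.0, 1.0, 5)
        p = SEIRDParams(alpha=0.1, beta_i=0.4, beta_e=0.4, delta=0.01,
                        gamma_i=0.05, gamma_e=0.1, A_e=10.0)
        state = uniform_state(mesh, s=0.0, e=0.0)
        with pytest.raises(ValueError, match="n_pop"):
            semidiscrete_residual(state, p)

    def test_zero_allee_parameter_gives_unit_factor(self):
        p = {"alpha": 0.1, "beta_i": 0.4, "beta_e": 0.4, "delta": 0.0,
             "gamma_i": 0.0, "gamma_e": 0.0, "A_e": 0.0}
        z = np.zeros(3)
        f = reaction_rates(p, z, z, z, z, z)  # n_pop = 0 must not divide
        np.testing.assert_array_equal(f["s"], 0.0)


class TestBDF2:
    def test_wellmixed_trajectory_matches_ode_oracle(self):
        mesh = build_interval_mesh(0.0, 1.0, 10)
        params = seird_1d_params()
        y0 = (0.3025, 0.0051, 0.0, 0.0, 0.0)  # domain means of the 1D scenario
        dt, n_steps = 0.25, 176
        traj, _ = run_fem_wellmixed(mesh, params, y0, dt, n_steps)
        oracle = wellmixed_oracle(params, y0, np.arange(n_steps + 1) * dt)
        err = np.linalg.norm(traj - oracle) / np.linalg.norm(oracle)
        assert err < 1e-4

    def test_temporal_self_convergence_is_second_order(self):
        mesh = build_interval_mesh(0.0, 1.0, 5)
        params = seird_1d_params()
        y0 = (1.0, 0.1, 0.01, 0.0, 0.0)  # vigorous dynamics stress the scheme
        t_end = 20.0
        errs = []
        oracle = wellmixed_oracle(params, y0, np.array([0.0, t_end]))[-1]
        for dt in (0.5, 0.25, 0.125):
            traj, _ = run_fem_wellmixed(mesh, params, y0, dt, int(t_end / dt))
            errs.append(np.linalg.norm(traj[-1] - oracle))
        slopes = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(slopes > 1.8) and np.all(slopes < 2.2)

    def test_population_conserved_with_neumann_bcs(self):
        mesh = build_interval_mesh(0.0, 1.0, 10)
        params = seird_1d_params()
        state = uniform_state(mesh, 0.3, 0.01)
        solver = SEIRDSolver(mesh, params, ALL_NEUMANN)
        pop0 = total_population(state)
        prev, cur = None, state
        for _ in range(40):
            new = solver.step(cur, prev, 0.25)
            prev, cur = cur, new
            assert abs(total_population(cur, normalize_by=pop0) - 1.0) < 1e-10

    def test_cumulative_compartment_integrates_incubation_flux(self):
        # dc/dt = alpha * e, so for near-constant e over a short window
        # c ~ alpha * e * t
        mesh = build_interval_mesh(0.0, 1.0, 5)
        params = SEIRDParams(alpha=0.2, beta_i=0.0, beta_e=0.0, delta=0.0,
                             gamma_i=0.0, gamma_e=0.0)
        state = uniform_state(mesh, s=1.0, e=0.5)
        solver = SEIRDSolver(mesh, params, ALL_NEUMANN)
        prev, cur = None, state
        for _ in range(8):
            new = solver.step(cur, prev, 0.125)
            prev, cur = cur, new
        # with beta = 0, e decays as exp(-alpha t); c = 0.5 (1 - exp(-alpha t))
        expected = 0.5 * (1.0 - np.exp(-0.2 * 1.0))
        assert cur.c[0] == pytest.approx(expected, rel=5e-3)

    def test_newton_failure_reports_diagnostics(self):
        mesh = build_interval_mesh(0.0, 1.0, 5)
        params = seird_1d_params()
        state = uniform_state(mesh, 1.0, 0.5, 0.2)
        solver = SEIRDSolver(mesh, params, ALL_NEUMANN, max_newton_iter=0)
        with pytest.raises(NewtonError, match="did not converge"):
            solver.step(state, None, 1.0)

    def test_dirichlet_boundary_enforced(self):
        mesh = build_interval_mesh(0.0, 1.0, 20)
        params = seird_1d_params()
        bcs = BCSpec({"left": "neumann", "right": "dirichlet0"})
        state = initial_conditions_1d(mesh)
        solver = SEIRDSolver(mesh, params, bcs)
        new = solver.step(state, None, 0.25)
        for comp in ("s", "e", "i", "r", "d"):
            assert abs(getattr(new, comp)[-1]) < 1e-12


class TestParams:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SEIRDParams(alpha=-0.1, beta_i=0.4, beta_e=0.4, delta=0.01,
                        gamma_i=0.05, gamma_e=0.1)

    def test_schedule_lookup(self):
        sched = Schedule([0.0, 10.0], [0.4, 0.1])
        assert sched(5.0) == 0.4
        assert sched(10.0) == 0.1
        with pytest.raises(ValueError, match="undefined"):
            sched(-1.0)

    def test_time_dependent_parameter_enters_rates(self):
        p = SEIRDParams(alpha=0.1, beta_i=Schedule([0.0, 5.0], [0.4, 0.0]),
                        beta_e=0.0, delta=0.0, gamma_i=0.0, gamma_e=0.0)
        assert p.at(1.0)["beta_i"] == 0.4
        assert p.at(6.0)["beta_i"] == 0.0


class TestTotalPopulation:
    def test_normalized_initial_value_is_one(self):
        mesh = build_interval_mesh(0.0, 1.0, 50)
        state = initial_conditions_1d(mesh)
        pop0 = total_population(state)
        assert total_population(state, normalize_by=pop0) == pytest.approx(1.0)

    def test_matches_field_integral(self):
        mesh = build_interval_mesh(0.0, 1.0, 30)
        state = initial_conditions_1d(mesh)
        direct = integrate(FEField(mesh, state.s + state.e + state.i + state.r + state.d))
        assert total_population(state) == pytest.approx(direct, abs=1e-14)
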