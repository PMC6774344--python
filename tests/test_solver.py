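"""Coupled PNP solver: residual identities, Newton, oracles, conservation,
symmetries, and time-scheme order."""

import numpy as np
import pytest

import gelpnp as g
from gelpnp.errors import ConvergenceError, OptionError, ScalingError
from gelpnp.fem import FunctionSpace
from gelpnp.solver import newton_solve, nondimensionalize

from _oracles import DensePnpSteady1D, fd_heat_backward_euler
from conftest import sample


def uniform_state(space, c=1.0, psi=0.0):
    return g.FieldState.uniform(space, {"Na+": c, "Cl-": c}, psi)


class TestWeakResiduals:
    def test_poisson_residual_zero_for_uniform_neutral_state(self, constants,
                                                             bath):
        params = g.validate_parameters(constants, bath.species,
                                       g.FixedChargeField(0.0), bath)
        mesh = g.build_interval_mesh(g.GeometrySpec.interval(base=1e-7,
                                                             fine=5e-8))
        space = FunctionSpace(mesh, 2)
        state = uniform_state(space, c=1.0, psi=0.123)
        r = g.poisson_residual(state, params, mesh, 2)
        # zero up to roundoff of the charge-density term gamma * c * h
        scale = (constants.faraday / constants.permittivity) * 1.0 * 5e-8
        assert np.max(np.abs(r)) < 1e-12 * scale

    def test_poisson_residual_sees_fixed_charge(self, params):
        mesh = g.build_interval_mesh(g.GeometrySpec.interval(base=1e-7,
                                                             fine=5e-8))
        space = FunctionSpace(mesh, 2)
        state = uniform_state(space)  # electroneutral pair, but c_f != 0
        r = g.poisson_residual(state, params, mesh, 2)
        assert np.max(np.abs(r)) > 0

    def test_nernst_planck_residual_zero_without_gradients(self, params):
        mesh = g.build_interval_mesh(g.GeometrySpec.interval(base=1e-7,
                                                             fine=5e-8))
        space = FunctionSpace(mesh, 2)
        state = uniform_state(space, c=2.0, psi=0.456)
        opts = g.SolverOptions(dt=0.1)
        r = g.nernst_planck_residual(state, state, params, opts, mesh, 2)
        # zero up to roundoff of the diffusion term D * c / h
        scale = 1e-7 * 2.0 / 5e-8
        assert np.max(np.abs(r)) < 1e-12 * scale

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(OptionError):
            g.SolverOptions(dt=0.0)


class TestNewton:
    def test_linear_problem_converges_in_one_iteration(
        self, params, coarse_interval_mesh
    ):
        """Poisson with frozen concentrations is linear: one Newton step."""
        import scipy.sparse as sp

        scaling = nondimensionalize(params, 1.5e-6)
        space = FunctionSpace(scaling.scale_mesh(coarse_interval_mesh), 2)
        gamma = 1.0 / scaling.debye_coefficient(params)
        K = space.stiffness_matrix().tolil()
        cf_q = 2.0 * space.region_indicator_q("gel")
        b = -gamma * space.load_vector(cf_q)  # z_f = -1, c+ = c- frozen at 1
        ends = np.unique(np.concatenate(
            [space.boundary_dofs("electrode_left"),
             space.boundary_dofs("electrode_right")]
        ))
        for d in ends:
            K.rows[d], K.data[d] = [int(d)], [1.0]
            b[d] = 0.0
        A = K.tocsr()

        class LinearSystem:
            def residual(self, u):
                return A @ u - b

            def jacobian(self, u):
                return sp.csr_matrix(A)

        u0 = np.zeros(space.ndof)
        _, iterations, history = newton_solve(
            LinearSystem(), u0, g.SolverOptions(newton_rel_tol=1e-10)
        )
        assert iterations == 1
        assert history[-1] < 1e-10 * history[0]

    def test_max_iterations_one_raises_on_nonlinear_problem(
        self, params, coarse_interval_mesh
    ):
        options = g.SolverOptions(max_newton_iterations=1)
        with pytest.raises(ConvergenceError) as exc:
            g.solve_chemical_equilibrium(params, coarse_interval_mesh,
                                         options=options)
        assert len(exc.value.history) >= 1


class TestChemicalEquilibrium:
    def test_matches_donnan_oracle(self, equilibrium, interval_mesh,
                                   donnan_oracle):
        got = sample(equilibrium, interval_mesh,
                     [[7.5e-7], [1.25e-7]])
        assert got["Na+"][0] == pytest.approx(donnan_oracle.gel_cation,
                                              rel=5e-3)
        assert got["Cl-"][0] == pytest.approx(donnan_oracle.gel_anion,
                                              rel=5e-3)
        jump = got["potential"][0] - got["potential"][1]
        assert jump == pytest.approx(donnan_oracle.potential_jump, rel=5e-3)

    def test_no_fixed_charge_gives_uniform_fields(self, constants, bath,
                                                  coarse_interval_mesh):
        params0 = g.validate_parameters(constants, bath.species,
                                        g.FixedChargeField(0.0), bath)
        state = g.solve_chemical_equilibrium(params0, coarse_interval_mesh)
        assert np.allclose(state.concentrations["Na+"], 1.0, atol=1e-9)
        assert np.allclose(state.concentrations["Cl-"], 1.0, atol=1e-9)
        assert np.max(np.abs(state.potential)) < 1e-12

    def test_symmetry_about_gel_center(self, equilibrium, interval_mesh):
        xs = np.array([2e-7, 4e-7, 6e-7, 7e-7])
        left = sample(equilibrium, interval_mesh, xs[:, None])
        right = sample(equilibrium, interval_mesh, (1.5e-6 - xs)[:, None])
        for name in ("Na+", "Cl-", "potential"):
            assert np.allclose(left[name], right[name], rtol=1e-6,
                               atol=1e-9)

    def test_matches_dense_brute_force_oracle(self, params):
        """P1 steady solve == independent dense-assembly Newton, <= 1e-6."""
        mesh = g.build_interval_mesh(
            g.GeometrySpec.interval(base=2e-8, fine=5e-9)
        )
        state = g.solve_chemical_equilibrium(params, mesh, discretization=1)
        scaling = nondimensionalize(params, 1.5e-6)
        xhat = np.sort(mesh.nodes[:, 0]) / scaling.length
        oracle = DensePnpSteady1D(
            xhat,
            (5e-7 / 1.5e-6, 1e-6 / 1.5e-6),
            gamma=1.0 / scaling.debye_coefficient(params),
            cf_hat=params.fixed_charge.concentration / scaling.concentration,
        )
        c1, c2, psi = oracle.solve()
        order = np.argsort(mesh.nodes[:, 0])
        ref_c1 = state.concentrations["Na+"][order] / scaling.concentration
        ref_c2 = state.concentrations["Cl-"][order] / scaling.concentration
        ref_psi = state.potential[order] / scaling.potential
        assert np.max(np.abs(ref_c1 - c1)) / np.max(np.abs(c1)) < 1e-6
        assert np.max(np.abs(ref_c2 - c2)) / np.max(np.abs(c2)) < 1e-6
        assert np.max(np.abs(ref_psi - psi)) / np.max(np.abs(psi)) < 1e-6


class TestTransient:
    def test_equilibrium_is_fixed_point_at_zero_volts(self, params,
                                                      interval_mesh,
                                                      equilibrium):
        protocol = g.electrical_protocol(params.bath, 0.0, "anode_left")
        options = g.SolverOptions(dt=2.5e-6, t_end=1.25e-5)
        result = g.run_transient(equilibrium, params, interval_mesh,
                                 protocol, options)
        first, last = result.states[0], result.states[-1]
        for name in ("Na+", "Cl-"):
            drift = np.max(np.abs(last.concentrations[name]
                                  - first.concentrations[name]))
            assert drift < 1e-7
        assert result.states[0].time == equilibrium.time

    def test_cathode_side_enrichment(self, electrical_result, interval_mesh):
        """50 mV, anode left: both ions higher in the gel on the cathode
        (right) side; solution concentrations rise at the cathode interface
        and drop at the anode interface."""
        final = electrical_result.states[-1]
        pts = np.array([[5.3e-7], [9.7e-7], [4.7e-7], [1.03e-6]])
        got = sample(final, interval_mesh, pts)
        for name in ("Na+", "Cl-"):
            anode_gel, cathode_gel, anode_sol, cathode_sol = got[name]
            assert cathode_gel > anode_gel
            assert cathode_sol > 1.0 > anode_sol

    def test_polarity_swap_mirrors_solution(self, params, interval_mesh,
                                            equilibrium):
        options = g.SolverOptions(dt=2.5e-7, t_end=2.5e-6)
        res_l = g.run_transient(
            equilibrium, params, interval_mesh,
            g.electrical_protocol(params.bath, 0.05, "anode_left"), options,
        )
        res_r = g.run_transient(
            equilibrium, params, interval_mesh,
            g.electrical_protocol(params.bath, 0.05, "anode_right"), options,
        )
        xs = np.array([1e-7, 5.3e-7, 7.5e-7, 9e-7])
        a = sample(res_l.states[-1], interval_mesh, xs[:, None])
        b = sample(res_r.states[-1], interval_mesh, (1.5e-6 - xs)[:, None])
        for name in ("Na+", "Cl-", "potential"):
            assert np.allclose(a[name], b[name], rtol=1e-8, atol=1e-10)

    def test_conservation_with_no_flux_everywhere(self, constants, bath):
        """All-insulated boundaries: total ion content per species constant
        to 1e-10 relative per step.

        Mild fixed charge on a layer-resolving mesh so the closed-box charge
        relaxation keeps concentrations positive.
        """
        params = g.validate_parameters(constants, bath.species,
                                       g.FixedChargeField(0.5), bath)
        mesh = g.build_interval_mesh(
            g.GeometrySpec.interval(band=1.0e-7, base=5e-8, fine=5e-9)
        )
        space = FunctionSpace(mesh, 2)
        bc = g.BoundaryConditions(
            potential={"electrode_left": None, "electrode_right": None},
            concentration={
                "electrode_left": {"Na+": None, "Cl-": None},
                "electrode_right": {"Na+": None, "Cl-": None},
            },
        )
        # a closed box must be globally electroneutral or Gauss's law has no
        # zero-flux solution: spread the counter-charge uniformly
        delta = (params.fixed_charge.concentration
                 * mesh.region_measure("gel")
                 / (mesh.region_measure("gel")
                    + mesh.region_measure("solution")))
        initial = g.FieldState.uniform(space, {"Na+": 1.0 + delta,
                                               "Cl-": 1.0})
        options = g.SolverOptions(dt=2.5e-7, t_end=2.5e-6,
                                  newton_abs_tol=1e-12)
        result = g.run_transient(initial, params, mesh, bc, options)
        totals = {"Na+": [], "Cl-": []}
        for s in result.states:
            for name in totals:
                cq, _ = space.at_quad(s.concentrations[name])
                totals[name].append(space.integrate(cq))
        for name, series in totals.items():
            series = np.array(series)
            steps = np.abs(np.diff(series)) / series[0]
            assert np.max(steps) < 1e-10
        # the charge relaxation it tracks is real: the state does change
        assert np.max(np.abs(result.states[-1].potential)) > 1e-4

    def test_pure_diffusion_matches_fd_oracle(self, constants, bath):
        """c+ = c- with no fixed charge: the PNP step is the heat equation;
        lumped-mass P1 on a uniform grid equals the FD scheme to 1e-8."""
        params0 = g.validate_parameters(constants, bath.species,
                                        g.FixedChargeField(0.0), bath)
        n = 60
        spec = g.GeometrySpec(1, (1.5e-6,), "interval", 2.5e-7, (7.5e-7,),
                              2e-7, 1.5e-6 / n, 1.5e-6 / n)
        mesh = g.build_interval_mesh(spec)
        space = FunctionSpace(mesh, g.Discretization(order=1,
                                                     lumped_mass=True))
        x = mesh.nodes[:, 0]
        bump = 1.0 + 0.5 * np.exp(-((x - 7.5e-7) / 2e-7) ** 2)
        initial = g.FieldState(0.0, {"Na+": bump.copy(), "Cl-": bump.copy()},
                               np.zeros(space.ndof))
        dt, steps = 2.5e-7, 8
        options = g.SolverOptions(dt=dt, t_end=dt * steps,
                                  newton_abs_tol=1e-14, lumped_mass=True)
        protocol = g.chemical_protocol(params0.bath)
        result = g.run_transient(initial, params0, mesh, protocol, options,
                                 discretization=g.Discretization(
                                     order=1, lumped_mass=True))
        ref = fd_heat_backward_euler(x, bump, 1.0e-7, dt, steps, 1.0)
        got = result.states[-1].concentrations["Na+"]
        assert np.max(np.abs(got - ref)) / np.max(ref) < 1e-8
        # neutrality held throughout, so no field developed
        assert np.max(np.abs(result.states[-1].potential)) < 1e-10

    def test_backward_euler_first_order_in_dt(self, params):
        """Error vs a tiny-dt reference halves with dt (first-order scheme)."""
        mesh = g.build_interval_mesh(
            g.GeometrySpec.interval(base=1e-7, fine=2.5e-8)
        )
        space = FunctionSpace(mesh, 2)
        initial = uniform_state(space)
        protocol = g.electrical_protocol(params.bath, 0.05, "anode_left")
        T = 2.0e-6

        def final_at(dt):
            options = g.SolverOptions(dt=dt, t_end=T, newton_abs_tol=1e-13)
            res = g.run_transient(initial, params, mesh, protocol, options)
            return res.states[-1]

        ref = final_at(T / 64)
        errors = []
        for dt in (T / 4, T / 8, T / 16):
            s = final_at(dt)
            err = max(
                np.max(np.abs(s.concentrations[n] - ref.concentrations[n]))
                for n in ("Na+", "Cl-")
            )
            errors.append(err)
        r1 = errors[0] / errors[1]
        r2 = errors[1] / errors[2]
        assert 1.5 < r1 < 3.0
        assert 1.5 < r2 < 3.0

    def test_halved_dt_same_steady_state(self, electrical_result,
                                         electrical_result_half_dt):
        a = electrical_result.states[-1]
        b = electrical_result_half_dt.states[-1]
        for name in ("Na+", "Cl-"):
            diff = np.max(np.abs(a.concentrations[name]
                                 - b.concentrations[name]))
            assert diff / np.max(a.concentrations[name]) < 1e-3


class TestNondimensionalize:
    def test_round_trip_identity(self, params, interval_mesh):
        scaling = nondimensionalize(params, 1.5e-6)
        space = FunctionSpace(interval_mesh, 2)
        state = g.FieldState(
            3.0,
            {"Na+": np.linspace(1, 2, space.ndof),
             "Cl-": np.linspace(2, 1, space.ndof)},
            np.linspace(-0.05, 0.05, space.ndof),
        )
        back = scaling.unscale_state(scaling.scale_state(state))
        assert back.time == pytest.approx(3.0, rel=1e-12)
        for name in state.concentrations:
            assert np.allclose(back.concentrations[name],
                               state.concentrations[name], rtol=1e-12)
        assert np.allclose(back.potential, state.potential, rtol=1e-12)
        mesh_back = scaling.scale_mesh(interval_mesh)
        assert np.allclose(mesh_back.nodes * scaling.length,
                           interval_mesh.nodes, rtol=1e-12)

    def test_thermal_voltage_scale(self, params):
        scaling = nondimensionalize(params, 0.015)
        assert scaling.potential == params.constants.thermal_voltage

    def test_debye_coefficient_against_direct_evaluation(self, params):
        """Dimensionless squared-Debye coefficient eps*R*T/(F^2 c L^2)."""
        L = 0.015
        scaling = nondimensionalize(params, L)
        k = params.constants
        direct = (k.relative_permittivity * k.vacuum_permittivity
                  * k.gas_constant * k.temperature
                  / (k.faraday ** 2 * 1.0 * L ** 2))
        assert scaling.debye_coefficient(params) == pytest.approx(direct,
                                                                  rel=1e-12)

    def test_zero_reference_concentration_rejected(self, constants):
        species = (g.IonSpecies("Na+", 1, 1e-7), g.IonSpecies("Cl-", -1, 1e-7))
        bath = g.BathComposition(species=species, molarity=(0.0, 0.0))
        ps = g.ParameterSet(constants, species[0], species[1],
                            g.FixedChargeField(1.0), bath)
        with pytest.raises(ScalingError):
            nondimensionalize(ps, 1.0)
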