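"""Profiles, steady-state detection, electroneutrality metric, export."""

import numpy as np
import pandas as pd
import pytest

import gelpnp as g
from gelpnp import postprocess as pp
from gelpnp.errors import ExtractionError
from gelpnp.fem import FunctionSpace


def synthetic_result(times, values, ndof=5):
    """TransientResult whose fields are spatially uniform at given values."""
    states = []
    for t, v in zip(times, values):
        states.append(g.FieldState(
            t,
            {"Na+": np.full(ndof, 1.0 + v), "Cl-": np.full(ndof, 1.0 + v)},
            np.full(ndof, v),
        ))
    return g.TransientResult(states=states, converged=True,
                             newton_iterations=[1] * (len(states) - 1),
                             steady_state_time=None)


class TestLineProfile:
    def test_constant_field_exact(self, interval_mesh):
        space = FunctionSpace(interval_mesh, 2)
        state = g.FieldState.uniform(space, {"Na+": 2.5, "Cl-": 0.5}, 0.125)
        prof = g.extract_line_profile(state, interval_mesh, n_samples=50)
        # exact up to the partition-of-unity roundoff of the basis
        assert np.allclose(prof.values["Na+"], 2.5, rtol=1e-14)
        assert np.allclose(prof.values["potential"], 0.125, rtol=1e-14)

    def test_linear_potential_exact(self, interval_mesh):
        space = FunctionSpace(interval_mesh, 2)
        psi = space.interpolate(lambda p: 3.0 * p[:, 0] - 1e-7)
        state = g.FieldState(0.0, {"Na+": np.ones(space.ndof),
                                   "Cl-": np.ones(space.ndof)}, psi)
        prof = g.extract_line_profile(state, interval_mesh, n_samples=77)
        assert np.allclose(prof.values["potential"],
                           3.0 * prof.coordinate - 1e-7, rtol=1e-12)

    def test_profile_scaling_commutes(self, equilibrium, interval_mesh):
        prof = g.extract_line_profile(equilibrium, interval_mesh,
                                      n_samples=64)
        scaled = equilibrium.copy()
        scaled.potential *= 7.0
        prof7 = g.extract_line_profile(scaled, interval_mesh, n_samples=64)
        assert np.allclose(prof7.values["potential"],
                           7.0 * prof.values["potential"], rtol=1e-12)

    def test_gel_plateau_at_donnan_values(self, equilibrium, interval_mesh,
                                          donnan_oracle):
        prof = g.extract_line_profile(equilibrium, interval_mesh,
                                      n_samples=400)
        x = prof.coordinate
        plateau = (x > 6.5e-7) & (x < 8.5e-7)  # > 10 Debye lengths inside
        assert np.mean(prof.values["Na+"][plateau]) == pytest.approx(
            donnan_oracle.gel_cation, rel=1e-3
        )
        assert np.mean(prof.values["Cl-"][plateau]) == pytest.approx(
            donnan_oracle.gel_anion, rel=1e-3
        )

    def test_line_outside_domain_rejected(self, equilibrium):
        spec = g.GeometrySpec(2, (1.0, 1.0), "square", 0.2, (0.5, 0.5),
                              0.1, 0.25, 0.25)
        mesh = g.build_square_gel_mesh(spec)
        space = FunctionSpace(mesh, 2)
        state = g.FieldState.uniform(space, {"Na+": 1.0, "Cl-": 1.0})
        with pytest.raises(ExtractionError):
            g.extract_line_profile(state, mesh, axis="x", offset=1.5)


class TestSteadyDetection:
    def test_constant_sequence_steady_from_start(self):
        res = synthetic_result([0.0, 1.0, 2.0, 3.0], [0.5, 0.5, 0.5, 0.5])
        assert g.detect_steady_state(res, 1e-8) == 0.0

    def test_oscillation_never_steady(self):
        res = synthetic_result([0.0, 1.0, 2.0, 3.0], [0.5, -0.5, 0.5, -0.5])
        assert g.detect_steady_state(res, 1e-3) is None

    def test_settling_sequence(self):
        times = list(range(8))
        # late blip at step 3->4 pushes the steady onset to t = 4
        values = [1.0, 0.5, 0.25, 0.2501, 0.25, 0.25, 0.25, 0.25]
        res = synthetic_result(times, values)
        t = g.detect_steady_state(res, 1e-5)
        assert t == 4.0

    def test_monotone_in_tolerance(self):
        times = np.linspace(0, 10, 21)
        values = np.exp(-times)
        res = synthetic_result(times, values)
        found = [g.detect_steady_state(res, tol)
                 for tol in (1e-6, 1e-4, 1e-2, 1.0)]
        numeric = [t for t in found if t is not None]
        assert numeric == sorted(numeric, reverse=True)

    def test_electrical_run_steady_time_stable_under_dt_halving(
        self, electrical_result, electrical_result_half_dt
    ):
        t1 = g.detect_steady_state(electrical_result, 10.0)
        t2 = g.detect_steady_state(electrical_result_half_dt, 10.0)
        assert t1 is not None and t2 is not None
        assert abs(t1 - t2) <= max(2 * 2.5e-7, 0.25 * t1)


class TestElectroneutrality:
    def test_donnan_analytic_state_is_neutral(self, params, interval_mesh,
                                              donnan_oracle):
        space = FunctionSpace(interval_mesh, 2)
        gel = space.dof_region_mask("gel")
        cp = np.where(gel, donnan_oracle.gel_cation, 1.0)
        cm = np.where(gel, donnan_oracle.gel_anion, 1.0)
        state = g.FieldState(0.0, {"Na+": cp, "Cl-": cm},
                             np.zeros(space.ndof))
        m = g.electroneutrality_metric(state, params, interval_mesh)
        assert m["norm_max"] < 1e-12

    def test_uniform_pair_reports_fixed_charge(self, params, interval_mesh):
        space = FunctionSpace(interval_mesh, 2)
        state = g.FieldState.uniform(space, {"Na+": 1.0, "Cl-": 1.0})
        m = g.electroneutrality_metric(state, params, interval_mesh)
        gel = space.dof_region_mask("gel")
        assert np.allclose(m["field"][gel], -2.0, atol=1e-14)
        assert np.allclose(m["field"][~gel], 0.0, atol=1e-14)

    def test_solved_equilibrium_bulk_neutral(self, equilibrium, params,
                                             interval_mesh):
        m = g.electroneutrality_metric(equilibrium, params, interval_mesh)
        assert m["norm_max_bulk"] <= 0.01  # <= 1% of the 1 mol/m^3 bath
        # and the double layers are genuinely charged
        assert m["norm_max"] > 10 * m["norm_max_bulk"]


class TestExport:
    def test_profile_csv_round_trip(self, equilibrium, interval_mesh,
                                    tmp_path):
        prof = g.extract_line_profile(equilibrium, interval_mesh,
                                      n_samples=64)
        path = tmp_path / "profile.csv"
        pp.export_profile_csv(prof, path)
        back = pd.read_csv(path)
        assert np.allclose(back["x [m]"], prof.coordinate, rtol=1e-15)
        assert np.allclose(back["Na+ [mol/m^3]"], prof.values["Na+"],
                           rtol=1e-15)
        assert np.allclose(back["potential [V]"], prof.values["potential"],
                           rtol=1e-15)

    def test_vtk_contains_all_fields_and_cells(self, equilibrium,
                                               interval_mesh, tmp_path):
        path = tmp_path / "state.vtk"
        pp.export_vtk(equilibrium, interval_mesh, path)
        text = path.read_text()
        assert f"CELL_TYPES {interval_mesh.n_cells}" in text
        assert f"POINTS {interval_mesh.n_nodes} double" in text
        for field in ("Na_plus", "Cl_minus", "potential"):
            assert f"SCALARS {field} double 1" in text

    def test_export_deterministic(self, equilibrium, interval_mesh, tmp_path):
        p1, p2 = tmp_path / "a.vtk", tmp_path / "b.vtk"
        pp.export_vtk(equilibrium, interval_mesh, p1)
        pp.export_vtk(equilibrium, interval_mesh, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_transient_export_writes_all_steps(self, tmp_path):
        res = synthetic_result([0.0, 1.0, 2.0], [0.1, 0.2, 0.3])
        mesh = g.build_interval_mesh(
            g.GeometrySpec.interval(base=4e-7, fine=4e-7)
        )
        ndof = mesh.n_nodes
        res = synthetic_result([0.0, 1.0, 2.0], [0.1, 0.2, 0.3], ndof=ndof)
        paths = g.export_fields(res, mesh, tmp_path)
        assert len(paths) == 3

    def test_checkpoint_round_trip(self, equilibrium, tmp_path):
        path = tmp_path / "state.npz"
        pp.save_checkpoint(equilibrium, path)
        back = pp.load_checkpoint(path)
        assert back.time == equilibrium.time
        for name in equilibrium.concentrations:
            assert np.array_equal(back.concentrations[name],
                                  equilibrium.concentrations[name])
        assert np.array_equal(back.potential, equilibrium.potential)
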