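"""Shared fixtures: validated parameter sets, scaled meshes, and solved states.

Expensive solves (chemical equilibrium, the 50 mV transient and its half-dt
twin) are session-scoped so the whole suite reuses them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import gelpnp as g

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants() -> g.PhysicalConstants:
    return g.PhysicalConstants()


@pytest.fixture(scope="session")
def bath() -> g.BathComposition:
    return g.BathComposition.nacl(1.0)


@pytest.fixture(scope="session")
def params(constants, bath) -> g.ParameterSet:
    return g.validate_parameters(
        constants, bath.species, g.FixedChargeField(2.0), bath
    )


@pytest.fixture(scope="session")
def interval_spec() -> g.GeometrySpec:
    # desk-scale variant of the validation geometry: all lengths / 1e4,
    # so the ~10 nm Debye layers are resolved by the 2 nm refined cells
    return g.GeometrySpec.interval()


@pytest.fixture(scope="session")
def interval_mesh(interval_spec) -> g.Mesh:
    return g.build_interval_mesh(interval_spec)


@pytest.fixture(scope="session")
def coarse_interval_mesh() -> g.Mesh:
    """Small 1D mesh (not Debye-resolving) for structural/algebraic tests."""
    spec = g.GeometrySpec.interval(base=1.0e-7, fine=2.5e-8)
    return g.build_interval_mesh(spec)


@pytest.fixture(scope="session")
def equilibrium(params, interval_mesh) -> g.FieldState:
    return g.solve_chemical_equilibrium(params, interval_mesh)


@pytest.fixture(scope="session")
def electrical_options() -> g.SolverOptions:
    return g.SolverOptions(dt=2.5e-7, t_end=5.0e-5, steady_tolerance=10.0)


@pytest.fixture(scope="session")
def electrical_result(params, interval_mesh, equilibrium, electrical_options):
    protocol = g.electrical_protocol(params.bath, 0.05, "anode_left")
    return g.run_transient(
        equilibrium, params, interval_mesh, protocol, electrical_options
    )


@pytest.fixture(scope="session")
def electrical_result_half_dt(params, interval_mesh, equilibrium,
                              electrical_options):
    from dataclasses import replace

    protocol = g.electrical_protocol(params.bath, 0.05, "anode_left")
    options = replace(electrical_options, dt=electrical_options.dt / 2)
    return g.run_transient(
        equilibrium, params, interval_mesh, protocol, options
    )


@pytest.fixture(scope="session")
def donnan_oracle(params) -> g.DonnanEquilibrium:
    return g.DonnanEquilibrium.solve(
        params.fixed_charge, params.bath, params.constants
    )


def sample(state, mesh, points, order=2):
    """Convenience: FE-interpolated field values at given points."""
    from gelpnp.fem import FunctionSpace
    from gelpnp.postprocess import sample_fields

    pts = np.atleast_2d(points)
    return sample_fields(state, FunctionSpace(mesh, order), pts)
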