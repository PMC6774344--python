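"""Coupled nonlinear Poisson-Nernst-Planck solver.

The unknowns are the two mobile ion concentrations c+ and c- and the electric
potential psi, discretized in a shared nodal Lagrange space and stacked as
(c+, c-, psi).  Two solve modes are provided:

* steady state (time term dropped) for the chemical-stimulation equilibrium
  and stationary electrical problems, via damped monolithic Newton with an
  analytic Jacobian and fixed-charge continuation as a fallback;
* backward-Euler transient stepping for the approach to steady state under
  electrical stimulation, with adaptive time-step halving on step failure.

The weak residuals are

    R_psi  = int grad(psi).grad(v) dx - (F/eps) int (z+ c+ + z- c- + z_f c_f) v dx
    R_k    = int (c_k - c_k_old)/dt v dx
             + int (D_k grad(c_k) + z_k mu_k c_k grad(psi)).grad(v) dx

with zero-flux (natural) conditions on insulated boundaries and Dirichlet
rows replaced in place.  By default the system is solved in nondimensional
form (potential in thermal-voltage units, concentrations relative to the
bath, lengths relative to the bath extent), which tames the F/eps ~ 1e14
coupling; results are transformed back to SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import ParameterSet
from .errors import (
    ConvergenceError,
    DimensionError,
    OptionError,
    ScalingError,
)
from .fem import Discretization, FunctionSpace, lumped_mass_matrix
from .geometry import Mesh
from .protocols import BoundaryConditions, Protocol, chemical_protocol

__all__ = [
    "FieldState",
    "SolverOptions",
    "TransientResult",
    "Nondimensionalization",
    "nondimensionalize",
    "PNPSystem",
    "newton_solve",
    "poisson_residual",
    "nernst_planck_residual",
    "solve_chemical_equilibrium",
    "run_transient",
    "state_change_rate",
]


# ---------------------------------------------------------------- field state

@dataclass
class FieldState:
    """Nodal values of both ion concentrations and the potential at one time.

    ``concentrations`` maps species name -> nodal array (mol m^-3);
    ``potential`` is the nodal potential (V).
    """

    time: float
    concentrations: dict[str, np.ndarray]
    potential: np.ndarray

    def copy(self) -> "FieldState":
        return FieldState(
            self.time,
            {k: v.copy() for k, v in self.concentrations.items()},
            self.potential.copy(),
        )

    def check_conforms(self, space: FunctionSpace) -> None:
        for name, c in self.concentrations.items():
            if c.shape != (space.ndof,):
                raise DimensionError(
                    f"concentration {name!r} has shape {c.shape}, "
                    f"expected ({space.ndof},)"
                )
        if self.potential.shape != (space.ndof,):
            raise DimensionError("potential does not conform to the space")

    def min_concentration(self) -> float:
        return min(float(c.min()) for c in self.concentrations.values())

    @classmethod
    def uniform(cls, space: FunctionSpace, concentrations: dict[str, float],
                potential: float = 0.0, time: float = 0.0) -> "FieldState":
        n = space.ndof
        return cls(
            time,
            {k: np.full(n, float(v)) for k, v in concentrations.items()},
            np.full(n, float(potential)),
        )


@dataclass(frozen=True)
class SolverOptions:
    """Newton / time-stepping controls.

    Tolerances apply to the RMS of the (nondimensional, by default) coupled
    residual.  ``dt``/``t_end`` are in seconds; ``steady_tolerance`` is a
    relative rate of change in 1/s at which a transient is considered steady
    (and, if ``stop_at_steady``, stopped early).
    """

    dt: float = 1.0
    t_end: float = 100.0
    newton_rel_tol: float = 1e-9
    newton_abs_tol: float = 1e-10
    max_newton_iterations: int = 30
    damping: float = 1.0
    linear_solver: str = "splu"
    nondimensionalize: bool = True
    steady_tolerance: float | None = None
    stop_at_steady: bool = True
    max_dt_retries: int = 12
    lumped_mass: bool = False

    def __post_init__(self):
        if not self.dt > 0.0:
            raise OptionError("dt must be positive")
        if not (self.newton_rel_tol > 0.0 and self.newton_abs_tol > 0.0):
            raise OptionError("Newton tolerances must be positive")
        if self.max_newton_iterations < 1:
            raise OptionError("max_newton_iterations must be >= 1")
        if not 0.0 < self.damping <= 1.0:
            raise OptionError("damping must lie in (0, 1]")


@dataclass
class TransientResult:
    """Time-ordered sequence of states from a backward-Euler run."""

    states: list[FieldState]
    converged: bool
    newton_iterations: list[int]
    steady_state_time: float | None
    dt_history: list[float] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])


# ------------------------------------------------------- nondimensionalization

@dataclass(frozen=True)
class Nondimensionalization:
    """Reference scales: x/L, c/c_ref, psi/(RT/F), t/(L^2/D_ref).

    The scaled thermal voltage is 1 by construction; the coefficient in front
    of the charge density in the scaled Poisson equation is
    gamma = F^2 c_ref L^2 / (eps R T), the inverse of the dimensionless
    squared-Debye-length coefficient.
    """

    length: float
    concentration: float
    potential: float
    diffusivity: float

    @property
    def time(self) -> float:
        return self.length ** 2 / self.diffusivity

    def scale_mesh(self, mesh: Mesh) -> Mesh:
        return Mesh(
            mesh.dim,
            mesh.nodes / self.length,
            mesh.cells,
            mesh.cell_regions,
            mesh.boundary_facets,
            mesh.boundary_tags,
            geometry=None,
        )

    def scale_state(self, state: FieldState) -> FieldState:
        return FieldState(
            state.time / self.time,
            {k: v / self.concentration for k, v in state.concentrations.items()},
            state.potential / self.potential,
        )

    def unscale_state(self, state: FieldState) -> FieldState:
        return FieldState(
            state.time * self.time,
            {k: v * self.concentration for k, v in state.concentrations.items()},
            state.potential * self.potential,
        )

    def debye_coefficient(self, params: ParameterSet) -> float:
        """eps_r eps0 R T / (F^2 c_ref L^2), the scaled squared Debye length."""
        k = params.constants
        return (k.permittivity * k.gas_constant * k.temperature
                / (k.faraday ** 2 * self.concentration * self.length ** 2))


def nondimensionalize(params: ParameterSet, reference_length: float) -> Nondimensionalization:
    """Build the scaling for a problem of the given geometric extent."""
    c_ref = max(params.bath.molarity)
    if not c_ref > 0.0:
        raise ScalingError("reference concentration must be positive")
    if not reference_length > 0.0:
        raise ScalingError("reference length must be positive")
    d_ref = max(s.diffusivity for s in params.species)
    return Nondimensionalization(
        length=reference_length,
        concentration=c_ref,
        potential=params.constants.thermal_voltage,
        diffusivity=d_ref,
    )


# ------------------------------------------------------------------- system

def _as_bc(bc) -> BoundaryConditions:
    if isinstance(bc, Protocol):
        return bc.boundary_conditions
    return bc


class PNPSystem:
    """Assembled residual/Jacobian of the coupled PNP equations.

    Unknown vector layout: [c_cation, c_anion, psi], each of length
    ``space.ndof``.  When ``scaling`` is given, the system (including the
    Dirichlet data) is expressed in nondimensional variables.
    """

    def __init__(
        self,
        space: FunctionSpace,
        params: ParameterSet,
        bc: BoundaryConditions | Protocol,
        scaling: Nondimensionalization | None = None,
        cf_fraction: float = 1.0,
    ):
        bc = _as_bc(bc)
        bc.validate(space.mesh)
        self.space = space
        self.params = params
        self.scaling = scaling
        self.n = space.ndof
        k = params.constants
        mu = [s.mobility_at(k) for s in params.species]
        self.z = np.array([s.valence for s in params.species], dtype=float)
        if scaling is None:
            self.gamma = k.faraday / k.permittivity
            self.D = np.array([s.diffusivity for s in params.species])
            self.drift = np.array([z * m for z, m in zip(self.z, mu)])
            cf_value = params.fixed_charge.concentration
        else:
            self.gamma = 1.0 / scaling.debye_coefficient(params)
            self.D = np.array(
                [s.diffusivity / scaling.diffusivity for s in params.species]
            )
            self.drift = np.array(
                [z * m * scaling.potential / scaling.diffusivity
                 for z, m in zip(self.z, mu)]
            )
            cf_value = params.fixed_charge.concentration / scaling.concentration

        self.K = space.stiffness_matrix()
        self.M = (lumped_mass_matrix(space) if space.disc.lumped_mass
                  else space.mass_matrix())
        cf_q = cf_value * cf_fraction * space.region_indicator_q(
            params.fixed_charge.region
        )
        self.b_cf = space.load_vector(
            self.gamma * params.fixed_charge.valence * cf_q
        )
        self._build_dirichlet(bc)
        self.u_old: np.ndarray | None = None
        self.dt: float | None = None

    # -- boundary conditions ------------------------------------------

    def _build_dirichlet(self, bc: BoundaryConditions) -> None:
        space, params, scaling = self.space, self.params, self.scaling
        idx, val = [], []
        tags = set(np.unique(space.mesh.boundary_tags).tolist())
        for tag in tags:
            dofs = space.boundary_dofs(tag)
            for ks, s in enumerate(params.species):
                c = bc.concentration[tag][s.name]
                if c is not None:
                    cval = c if scaling is None else c / scaling.concentration
                    idx.append(dofs + ks * self.n)
                    val.append(np.full(len(dofs), cval))
            v = bc.potential[tag]
            if v is not None:
                vval = v if scaling is None else v / scaling.potential
                idx.append(dofs + 2 * self.n)
                val.append(np.full(len(dofs), vval))
        if not any(bc.potential[t] is not None for t in tags):
            # pure-Neumann Poisson block is singular: pin one potential dof
            idx.append(np.array([2 * self.n]))
            val.append(np.array([0.0]))
        if idx:
            self.dirichlet_idx = np.concatenate(idx)
            self.dirichlet_val = np.concatenate(val)
        else:
            self.dirichlet_idx = np.empty(0, dtype=np.int64)
            self.dirichlet_val = np.empty(0)
        keep = np.ones(3 * self.n)
        keep[self.dirichlet_idx] = 0.0
        self._keep = keep
        ind = np.zeros(3 * self.n)
        ind[self.dirichlet_idx] = 1.0
        self._indicator_diag = sp.diags(ind).tocsr()

    def apply_dirichlet_to_state(self, u: np.ndarray) -> np.ndarray:
        u = u.copy()
        u[self.dirichlet_idx] = self.dirichlet_val
        return u

    # -- state conversion ---------------------------------------------

    def split(self, u: np.ndarray):
        n = self.n
        return [u[0:n], u[n:2 * n]], u[2 * n:3 * n]

    def state_to_vector(self, state: FieldState) -> np.ndarray:
        state.check_conforms(self.space)
        if self.scaling is not None:
            state = self.scaling.scale_state(state)
        parts = [state.concentrations[s.name] for s in self.params.species]
        return np.concatenate(parts + [state.potential])

    def vector_to_state(self, u: np.ndarray, time: float = 0.0) -> FieldState:
        cs, psi = self.split(u)
        state = FieldState(
            time,
            {s.name: c.copy() for s, c in zip(self.params.species, cs)},
            psi.copy(),
        )
        if self.scaling is not None:
            state = self.scaling.unscale_state(state)
            state.time = time
        return state

    # -- stepping context ---------------------------------------------

    def set_step(self, u_old: np.ndarray | None, dt: float | None) -> None:
        """Configure transient stepping; ``None`` selects the steady system."""
        if dt is not None and not dt > 0.0:
            raise OptionError("dt must be positive")
        self.u_old = None if u_old is None else u_old.copy()
        self.dt = dt

    # -- residual and Jacobian ----------------------------------------

    def residual(self, u: np.ndarray) -> np.ndarray:
        cs, psi = self.split(u)
        _, grad_psi = self.space.at_quad(psi)
        r = np.empty(3 * self.n)
        r_psi = self.K @ psi - self.b_cf
        A = self.space.drift_matrix(grad_psi)
        for kth, c in enumerate(cs):
            r_psi -= self.gamma * self.z[kth] * (self.M @ c)
            rk = self.D[kth] * (self.K @ c) + self.drift[kth] * (A @ c)
            if self.dt is not None:
                c_old = self.split(self.u_old)[0][kth]
                rk += (self.M @ (c - c_old)) / self.dt
            r[kth * self.n:(kth + 1) * self.n] = rk
        r[2 * self.n:] = r_psi
        r[self.dirichlet_idx] = u[self.dirichlet_idx] - self.dirichlet_val
        return r

    def jacobian(self, u: np.ndarray) -> sp.csr_matrix:
        cs, psi = self.split(u)
        _, grad_psi = self.space.at_quad(psi)
        A = self.space.drift_matrix(grad_psi)
        blocks: list[list] = [[None] * 3 for _ in range(3)]
        for kth, c in enumerate(cs):
            Jkk = self.D[kth] * self.K + self.drift[kth] * A
            if self.dt is not None:
                Jkk = Jkk + self.M / self.dt
            c_q, _ = self.space.at_quad(c)
            blocks[kth][kth] = Jkk
            blocks[kth][2] = self.drift[kth] * self.space.stiffness_matrix(c_q)
            blocks[2][kth] = -self.gamma * self.z[kth] * self.M
        blocks[2][2] = self.K
        J = sp.bmat(blocks, format="csr")
        # replace Dirichlet rows by identity rows
        J = sp.diags(self._keep).tocsr() @ J + self._indicator_diag
        return J.tocsr()


# -------------------------------------------------------------------- newton

def _rms(r: np.ndarray) -> float:
    return float(np.sqrt(np.mean(r * r)))


def newton_solve(
    system,
    u0: np.ndarray,
    options: SolverOptions,
) -> tuple[np.ndarray, int, list[float]]:
    """Damped Newton iteration on ``system`` (residual/jacobian callables).

    Returns ``(solution, iterations, residual_history)``; raises
    :class:`~gelpnp.errors.ConvergenceError` carrying the history when the
    iteration exhausts ``max_newton_iterations`` or stagnates.
    """
    u = u0.copy()
    r = system.residual(u)
    history = [_rms(r)]
    r0 = max(history[0], 1e-300)
    rejected_in_a_row = 0
    for it in range(options.max_newton_iterations + 1):
        if history[-1] <= options.newton_abs_tol or (
            history[-1] <= options.newton_rel_tol * r0
        ):
            return u, it, history
        if it == options.max_newton_iterations:
            break
        J = system.jacobian(u)
        du = spla.spsolve(J.tocsc(), -r)
        if not np.all(np.isfinite(du)):
            raise ConvergenceError("linear solve produced non-finite update",
                                   history)
        alpha = options.damping
        accepted = False
        for _ in range(10):
            u_try = u + alpha * du
            r_try = system.residual(u_try)
            n_try = _rms(r_try)
            if np.isfinite(n_try) and n_try < (1.0 - 1e-4 * alpha) * history[-1]:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            rejected_in_a_row += 1
            if rejected_in_a_row >= 2:
                raise ConvergenceError(
                    "Newton stagnated: line search failed twice "
                    f"(residual {history[-1]:.3e})",
                    history,
                )
        else:
            rejected_in_a_row = 0
        u, r = u_try, r_try
        history.append(n_try)
    raise ConvergenceError(
        f"Newton did not converge in {options.max_newton_iterations} "
        f"iterations (residual {history[-1]:.3e})",
        history,
    )


# ------------------------------------------------------- public weak residuals

def poisson_residual(
    state: FieldState,
    params: ParameterSet,
    mesh: Mesh,
    discretization: Discretization | int = 2,
) -> np.ndarray:
    """SI weak residual of the Poisson equation at ``state``.

    Natural (zero normal flux) boundary conditions; Dirichlet rows are the
    business of the boundary-condition machinery and are not applied here.
    Zero iff the state satisfies the discrete Poisson equation.
    """
    space = FunctionSpace(mesh, discretization)
    state.check_conforms(space)
    k = params.constants
    gamma = k.faraday / k.permittivity
    _, grad_psi = space.at_quad(state.potential)
    K = space.stiffness_matrix()
    r = K @ state.potential
    for s in params.species:
        c_q, _ = space.at_quad(state.concentrations[s.name])
        r -= space.load_vector(gamma * s.valence * c_q)
    fc = params.fixed_charge
    cf_q = fc.concentration * space.region_indicator_q(fc.region)
    r -= space.load_vector(gamma * fc.valence * cf_q)
    return r


def nernst_planck_residual(
    state_new: FieldState,
    state_old: FieldState,
    params: ParameterSet,
    options: SolverOptions,
    mesh: Mesh,
    discretization: Discretization | int = 2,
) -> np.ndarray:
    """SI weak residual of one backward-Euler Nernst-Planck step.

    Drift and diffusion are evaluated implicitly at ``state_new``; zero-flux
    natural conditions on all boundaries.  Returns the stacked per-species
    residual (cation block first).
    """
    if not options.dt > 0.0:
        raise OptionError("dt must be positive")
    space = FunctionSpace(mesh, discretization)
    state_new.check_conforms(space)
    state_old.check_conforms(space)
    k = params.constants
    K = space.stiffness_matrix()
    M = lumped_mass_matrix(space) if space.disc.lumped_mass else space.mass_matrix()
    _, grad_psi = space.at_quad(state_new.potential)
    A = space.drift_matrix(grad_psi)
    out = []
    for s in params.species:
        c = state_new.concentrations[s.name]
        c_old = state_old.concentrations[s.name]
        drift = s.valence * s.mobility_at(k)
        out.append(
            (M @ (c - c_old)) / options.dt
            + s.diffusivity * (K @ c)
            + drift * (A @ c)
        )
    return np.concatenate(out)


# --------------------------------------------------------------- steady solve

def _build_system(params, mesh, bc, options, discretization, cf_fraction=1.0):
    disc = (discretization if isinstance(discretization, Discretization)
            else Discretization(order=discretization,
                                lumped_mass=options.lumped_mass))
    if options.lumped_mass and not disc.lumped_mass:
        disc = replace(disc, lumped_mass=True)
    space = FunctionSpace(mesh, disc)
    scaling = None
    if options.nondimensionalize:
        extent = float(np.ptp(mesh.nodes[:, 0]))
        scaling = nondimensionalize(params, extent)
        space = FunctionSpace(scaling.scale_mesh(mesh), disc)
    system = PNPSystem(space, params, bc, scaling=scaling,
                       cf_fraction=cf_fraction)
    return system


def solve_chemical_equilibrium(
    params: ParameterSet,
    mesh: Mesh,
    bc: BoundaryConditions | Protocol | None = None,
    options: SolverOptions | None = None,
    discretization: Discretization | int = 2,
) -> FieldState:
    """Steady-state solve of the chemical-stimulation scenario.

    Boundary data defaults to the chemical protocol (concentrations at bath
    values, 0 V at both electrodes).  Starts Newton from the uniform bath
    state; if the fully charged gel does not converge directly, the fixed
    charge is ramped up in fractions (parameter continuation), each stage
    warm-started from the previous.  In the bulk of the gel the solution
    matches the closed-form Donnan equilibrium.
    """
    options = options or SolverOptions()
    protocol = bc if bc is not None else chemical_protocol(params.bath)
    uniform = {s.name: params.bath_concentration(s) for s in params.species}
    system = _build_system(params, mesh, protocol, options, discretization)
    init = FieldState.uniform(system.space, uniform)  # only ndof is used
    u0 = system.apply_dirichlet_to_state(system.state_to_vector(init))
    try:
        u, _, _ = newton_solve(system, u0, options)
    except ConvergenceError:
        u = u0
        for frac in (0.25, 0.5, 0.75, 1.0):
            system = _build_system(params, mesh, protocol, options,
                                   discretization, cf_fraction=frac)
            u = system.apply_dirichlet_to_state(u)
            u, _, _ = newton_solve(system, u, options)
    return system.vector_to_state(u, time=0.0)


# ------------------------------------------------------------------ transient

def state_change_rate(s0: FieldState, s1: FieldState) -> float:
    """max over fields of ||df||_inf / ||f||_inf / dt, in 1/s."""
    dt = s1.time - s0.time
    if not dt > 0.0:
        raise OptionError("states must be strictly increasing in time")
    rate = 0.0
    pairs = [(s0.potential, s1.potential)]
    pairs += [
        (s0.concentrations[k], s1.concentrations[k]) for k in s1.concentrations
    ]
    for f0, f1 in pairs:
        dn = float(np.max(np.abs(f1 - f0)))
        if dn == 0.0:
            continue
        fn = float(np.max(np.abs(f1)))
        rate = max(rate, dn / max(fn, 1e-300) / dt)
    return rate


def run_transient(
    initial: FieldState,
    params: ParameterSet,
    mesh: Mesh,
    bc: BoundaryConditions | Protocol,
    options: SolverOptions,
    discretization: Discretization | int = 2,
) -> TransientResult:
    """Backward-Euler time integration from ``initial`` to ``t_end``.

    Each step is solved by Newton warm-started from the previous state.  A
    failed step (non-convergence or a concentration below -1e-12 c_ref) is
    retried with the step halved, up to ``max_dt_retries``; after five
    consecutive successes the step is doubled back toward the nominal ``dt``.
    With ``steady_tolerance`` set, the run is cut short (``stop_at_steady``)
    once the relative rate of change stays below tolerance for three steps.
    """
    system = _build_system(params, mesh, bc, options, discretization)
    c_ref = max(params.bath.molarity)
    u = system.state_to_vector(initial)
    u = system.apply_dirichlet_to_state(u)
    first = initial.copy()
    states = [first]
    newton_counts: list[int] = []
    dt_history: list[float] = []
    t = initial.time
    dt_nominal = options.dt
    dt = dt_nominal
    steady_time: float | None = None
    steady_run = 0
    successes = 0
    converged = True
    while t < options.t_end - 1e-12 * options.t_end:
        dt_step = min(dt, options.t_end - t)
        retries = 0
        while True:
            dt_scaled = (dt_step if system.scaling is None
                         else dt_step / system.scaling.time)
            system.set_step(u, dt_scaled)
            guess = system.apply_dirichlet_to_state(u)
            try:
                u_new, its, _ = newton_solve(system, guess, options)
                cs, _ = system.split(u_new)
                floor = -1e-12 * (1.0 if system.scaling is not None else c_ref)
                if min(c.min() for c in cs) < floor:
                    raise ConvergenceError(
                        "step produced a negative concentration", []
                    )
                break
            except ConvergenceError:
                retries += 1
                successes = 0
                if retries > options.max_dt_retries:
                    raise
                dt_step *= 0.5
                dt = dt_step
        successes += 1
        if successes >= 5 and dt < dt_nominal:
            dt = min(2.0 * dt, dt_nominal)
            successes = 0
        t += dt_step
        u = u_new
        state = system.vector_to_state(u, time=t)
        newton_counts.append(its)
        dt_history.append(dt_step)
        rate = state_change_rate(states[-1], state)
        states.append(state)
        if options.steady_tolerance is not None:
            if rate <= options.steady_tolerance:
                steady_run += 1
                if steady_time is None:
                    steady_time = t
                if options.stop_at_steady and steady_run >= 3:
                    break
            else:
                steady_run = 0
                steady_time = None
    return TransientResult(
        states=states,
        converged=converged,
        newton_iterations=newton_counts,
        steady_state_time=steady_time,
        dt_history=dt_history,
    )
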