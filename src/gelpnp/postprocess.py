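"""Profile extraction, steady-state detection, diagnostics, and field export.

Profiles are sampled with the discretization's own basis (exact for fields in
the FE space); steady state is declared at the earliest time after which the
relative rate of change of every field stays below tolerance; the
electroneutrality metric is the net charge concentration
sum_k z_k c_k + z_f c_f per node, with an interface-excluded variant that
masks the electric-double-layer region within N Debye lengths of the
gel-solution interface.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ParameterSet
from .errors import ExtractionError, GelPnpError
from .fem import Discretization, FunctionSpace
from .geometry import Mesh
from .solver import FieldState, TransientResult, state_change_rate

__all__ = [
    "LineProfile",
    "DiagnosticSeries",
    "extract_line_profile",
    "detect_steady_state",
    "electroneutrality_metric",
    "debye_length",
    "export_vtk",
    "export_profile_csv",
    "export_fields",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class LineProfile:
    """Fields sampled along an axis-parallel line.

    ``coordinate`` is the along-line coordinate (m, strictly increasing);
    ``values`` maps field name -> samples; ``axis``/``offset`` record the
    sampling line (offset is the fixed transverse coordinate, 2D only).
    """

    coordinate: np.ndarray
    values: dict[str, np.ndarray]
    axis: str
    offset: float | None = None

    def __post_init__(self):
        if len(self.coordinate) < 2:
            raise ExtractionError("a profile needs at least 2 sample points")
        if not np.all(np.diff(self.coordinate) > 0):
            raise ExtractionError("profile coordinates must be strictly increasing")


@dataclass
class DiagnosticSeries:
    """Per-step diagnostic metrics of a transient run."""

    times: np.ndarray
    metrics: dict[str, np.ndarray]

    def __post_init__(self):
        for name, v in self.metrics.items():
            if len(v) != len(self.times):
                raise GelPnpError(f"metric {name!r} length mismatch")
        if not np.all(np.diff(self.times) > 0):
            raise GelPnpError("diagnostic times must be strictly increasing")


# ----------------------------------------------------------------- sampling

def _locate_points_1d(space: FunctionSpace, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mesh = space.mesh
    x0 = mesh.nodes[mesh.cells[:, 0], 0]
    x1 = mesh.nodes[mesh.cells[:, 1], 0]
    order = np.argsort(x0)
    lo, hi = x0[order], x1[order]
    tol = 1e-12 * (hi[-1] - lo[0])
    if np.any(x < lo[0] - tol) or np.any(x > hi[-1] + tol):
        raise ExtractionError("sample point outside the domain")
    idx = np.clip(np.searchsorted(lo, x + tol) - 1, 0, len(lo) - 1)
    cells = order[idx]
    xi = (x - x0[cells]) / (x1[cells] - x0[cells])
    return cells, np.clip(xi, 0.0, 1.0)[:, None]


def _locate_points_2d(space: FunctionSpace, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mesh = space.mesh
    p = mesh.nodes[mesh.cells]  # (nc, 3, 2)
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    cells = np.full(len(pts), -1, dtype=np.int64)
    bary = np.zeros((len(pts), 2))
    tol = -1e-10
    for i, q in enumerate(pts):
        r = q - p[:, 0]
        xi = (r[:, 0] * d2[:, 1] - r[:, 1] * d2[:, 0]) / det
        eta = (d1[:, 0] * r[:, 1] - d1[:, 1] * r[:, 0]) / det
        ok = (xi >= tol) & (eta >= tol) & (xi + eta <= 1.0 - tol)
        hits = np.nonzero(ok)[0]
        if len(hits) == 0:
            raise ExtractionError(
                f"sample point ({q[0]:g}, {q[1]:g}) outside the domain"
            )
        cells[i] = hits[0]
        bary[i] = (xi[hits[0]], eta[hits[0]])
    return cells, bary


def _basis_at(space: FunctionSpace, ref: np.ndarray) -> np.ndarray:
    """Basis values at reference coordinates ref (npts, dim_ref)."""
    order = space.order
    if space.mesh.dim == 1:
        xs = np.array([0.0, 1.0] + [(i + 1) / order for i in range(order - 1)])
        V = np.vander(xs, increasing=True)
        C = np.linalg.inv(V)
        P = np.vander(ref[:, 0], N=order + 1, increasing=True)
        return P @ C
    xi, eta = ref[:, 0], ref[:, 1]
    l0, l1, l2 = 1.0 - xi - eta, xi, eta
    if order == 1:
        return np.column_stack([l0, l1, l2])
    return np.column_stack([
        l0 * (2 * l0 - 1), l1 * (2 * l1 - 1), l2 * (2 * l2 - 1),
        4 * l0 * l1, 4 * l1 * l2, 4 * l2 * l0,
    ])


def sample_fields(
    state: FieldState,
    space: FunctionSpace,
    points: np.ndarray,
) -> dict[str, np.ndarray]:
    """Evaluate all fields of ``state`` at arbitrary points (FE interpolation)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if space.mesh.dim == 1:
        cells, ref = _locate_points_1d(space, points[:, 0])
    else:
        cells, ref = _locate_points_2d(space, points)
    N = _basis_at(space, ref)
    out = {}
    fields = {**state.concentrations, "potential": state.potential}
    for name, u in fields.items():
        uc = u[space.cell_dofs[cells]]
        out[name] = np.einsum("pi,pi->p", N, uc)
    return out


def extract_line_profile(
    state: FieldState,
    mesh: Mesh,
    axis: str = "x",
    offset: float | None = None,
    n_samples: int = 200,
    discretization: Discretization | int = 2,
    space: FunctionSpace | None = None,
) -> LineProfile:
    """Sample all fields along an axis-parallel line through the domain.

    ``offset`` is the fixed transverse coordinate (2D only; defaults to the
    domain midline).  Points outside the domain raise; nothing is
    extrapolated.
    """
    space = space or FunctionSpace(mesh, discretization)
    if axis not in ("x", "y"):
        raise ExtractionError("axis must be 'x' or 'y'")
    if mesh.dim == 1 and axis != "x":
        raise ExtractionError("1D meshes have only an x axis")
    ax = 0 if axis == "x" else 1
    lo = float(mesh.nodes[:, ax].min())
    hi = float(mesh.nodes[:, ax].max())
    coord = np.linspace(lo, hi, n_samples)
    if mesh.dim == 1:
        points = coord[:, None]
    else:
        other = 1 - ax
        if offset is None:
            offset = 0.5 * float(mesh.nodes[:, other].min()
                                 + mesh.nodes[:, other].max())
        o_lo = float(mesh.nodes[:, other].min())
        o_hi = float(mesh.nodes[:, other].max())
        if not o_lo <= offset <= o_hi:
            raise ExtractionError("sampling line lies outside the domain")
        points = np.empty((n_samples, 2))
        points[:, ax] = coord
        points[:, other] = offset
    values = sample_fields(state, space, points)
    return LineProfile(coordinate=coord, values=values, axis=axis,
                       offset=None if mesh.dim == 1 else offset)


# ------------------------------------------------------------- steady state

def detect_steady_state(result: TransientResult, tolerance: float = 1e-8) -> float | None:
    """Earliest time t* after which the relative rate of change of every
    field stays below ``tolerance`` (1/s) for all later step pairs.

    Returns ``None`` when the sequence never settles.  Monotone in the
    tolerance: a larger tolerance never yields a later t*.
    """
    states = result.states
    if len(states) < 2:
        raise GelPnpError("steady-state detection needs at least 2 states")
    rates = [state_change_rate(a, b) for a, b in zip(states[:-1], states[1:])]
    above = [i for i, r in enumerate(rates) if r > tolerance]
    if not above:
        return states[0].time
    last = above[-1]
    if last == len(rates) - 1:
        return None
    return states[last + 1].time


# --------------------------------------------------------- electroneutrality

def debye_length(params: ParameterSet, concentration: float | None = None) -> float:
    """sqrt(eps R T / (2 F^2 c)) at the bath concentration by default."""
    k = params.constants
    c = max(params.bath.molarity) if concentration is None else concentration
    return math.sqrt(
        k.permittivity * k.gas_constant * k.temperature / (2.0 * k.faraday ** 2 * c)
    )


def electroneutrality_metric(
    state: FieldState,
    params: ParameterSet,
    mesh: Mesh,
    discretization: Discretization | int = 2,
    exclude_debye_lengths: float = 5.0,
    space: FunctionSpace | None = None,
) -> dict:
    """Net charge concentration sum_k z_k c_k + z_f c_f per nodal dof.

    Returns the nodal field, its max-norm, and an interface-excluded max-norm
    computed on dofs farther than ``exclude_debye_lengths`` Debye lengths
    from the gel-solution interface (where the double layers live).  Nodes on
    the closed gel region count as gel for the fixed-charge indicator.
    """
    space = space or FunctionSpace(mesh, discretization)
    state.check_conforms(space)
    rho = np.zeros(space.ndof)
    for s in params.species:
        rho += s.valence * state.concentrations[s.name]
    fc = params.fixed_charge
    gel = space.dof_region_mask(fc.region)
    rho[gel] += fc.valence * fc.concentration
    iface = mesh.interface_nodes()
    if len(iface):
        from scipy.spatial import cKDTree

        tree = cKDTree(np.atleast_2d(mesh.nodes[iface]))
        dist, _ = tree.query(space.dof_coords)
        mask = dist > exclude_debye_lengths * debye_length(params)
    else:
        mask = np.ones(space.ndof, dtype=bool)
    bulk = float(np.max(np.abs(rho[mask]))) if mask.any() else 0.0
    return {
        "field": rho,
        "norm_max": float(np.max(np.abs(rho))),
        "norm_max_bulk": bulk,
        "bulk_mask": mask,
    }


def diagnostics(result: TransientResult, params: ParameterSet, mesh: Mesh,
                discretization: Discretization | int = 2) -> DiagnosticSeries:
    """Per-step rate of change, total ion content, charge norm, min c."""
    space = FunctionSpace(mesh, discretization)
    times, rate, mins, charge = [], [], [], []
    totals: dict[str, list[float]] = {
        name: [] for name in result.states[0].concentrations
    }
    for prev, s in zip(result.states[:-1], result.states[1:]):
        times.append(s.time)
        rate.append(state_change_rate(prev, s))
        mins.append(s.min_concentration())
        em = electroneutrality_metric(s, params, mesh, discretization,
                                      space=space)
        charge.append(em["norm_max_bulk"])
        for name, c in s.concentrations.items():
            cq, _ = space.at_quad(c)
            totals[name].append(space.integrate(cq))
    metrics = {"rate": np.array(rate), "min_concentration": np.array(mins),
               "bulk_charge_norm": np.array(charge)}
    for name, v in totals.items():
        metrics[f"total_{name}"] = np.array(v)
    return DiagnosticSeries(times=np.array(times), metrics=metrics)


# ------------------------------------------------------------------- export

def export_vtk(state: FieldState, mesh: Mesh, path: str | os.PathLike) -> None:
    """Write one state as a legacy-VTK ASCII unstructured grid.

    Only vertex values are written (fields are P1-subsampled for
    visualization); output is byte-deterministic for identical inputs.
    """
    nv = mesh.n_nodes
    lines = [
        "# vtk DataFile Version 3.0",
        "gelpnp fields",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {nv} double",
    ]
    for p in mesh.nodes:
        x = float(p[0])
        y = float(p[1]) if mesh.dim == 2 else 0.0
        lines.append(f"{x!r} {y!r} 0.0")
    nper = mesh.cells.shape[1]
    lines.append(f"CELLS {mesh.n_cells} {mesh.n_cells * (nper + 1)}")
    for c in mesh.cells:
        lines.append(f"{nper} " + " ".join(str(int(v)) for v in c))
    vtk_type = 3 if mesh.dim == 1 else 5  # line / triangle
    lines.append(f"CELL_TYPES {mesh.n_cells}")
    lines += [str(vtk_type)] * mesh.n_cells
    lines.append(f"POINT_DATA {nv}")
    fields = {**state.concentrations, "potential": state.potential}
    for name, u in fields.items():
        safe = name.replace("+", "_plus").replace("-", "_minus")
        lines.append(f"SCALARS {safe} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [repr(float(v)) for v in u[:nv]]
    lines.append(f"CELL_DATA {mesh.n_cells}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += ["1" if r == "gel" else "2" for r in mesh.cell_regions]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_UNITS = {"potential": "V"}


def export_profile_csv(profile: LineProfile, path: str | os.PathLike) -> None:
    """Write a line profile as CSV with a unit-annotated header."""
    cols = {f"{profile.axis} [m]": profile.coordinate}
    for name, v in profile.values.items():
        unit = _UNITS.get(name, "mol/m^3")
        cols[f"{name} [{unit}]"] = v
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def export_fields(
    result: TransientResult | FieldState,
    mesh: Mesh,
    directory: str | os.PathLike,
    basename: str = "fields",
) -> list[str]:
    """Write a state (or every state of a transient) as VTK time series."""
    os.makedirs(directory, exist_ok=True)
    states = result.states if isinstance(result, TransientResult) else [result]
    paths = []
    for i, s in enumerate(states):
        p = os.path.join(directory, f"{basename}_{i:04d}.vtk")
        export_vtk(s, mesh, p)
        paths.append(p)
    return paths


# --------------------------------------------------------------- checkpoints

def save_checkpoint(state: FieldState, path: str | os.PathLike) -> None:
    """Save a FieldState as an .npz archive with a small metadata header."""
    names = sorted(state.concentrations)
    np.savez(
        path,
        time=np.array([state.time]),
        species=np.array(names),
        potential=state.potential,
        **{f"c_{i}": state.concentrations[n] for i, n in enumerate(names)},
    )


def load_checkpoint(path: str | os.PathLike) -> FieldState:
    with np.load(path, allow_pickle=False) as data:
        names = [str(n) for n in data["species"]]
        return FieldState(
            time=float(data["time"][0]),
            concentrations={n: data[f"c_{i}"] for i, n in enumerate(names)},
            potential=data["potential"],
        )
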