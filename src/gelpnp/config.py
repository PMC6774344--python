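"""Run configuration schema, bundled presets, and scenario orchestration.

Configurations are JSON or TOML documents validated against a strict schema
(unknown keys rejected, errors reported with their key path).  Bundled
presets reproduce the two study scenarios — chemical equilibration of a
2 mol/m^3 fixed-charge gel in a 1 mM NaCl bath, and 50 mV constant-voltage
stimulation started from that equilibrium — at full scale and in a
desk-scale variant with all lengths shrunk by 1e4 so that the Debye layers
(~10 nm at 1 mM, eps_r = 100) are mesh-resolvable.  Bulk Donnan values are
geometry-independent, which is what makes the scaled variant quantitative.
"""

from __future__ import annotations

import json
import os
import tomllib
from importlib import resources
from typing import Literal

import numpy as np
import pydantic
from pydantic import BaseModel, ConfigDict, Field

from . import postprocess
from .core import (
    BathComposition,
    DonnanEquilibrium,
    FixedChargeField,
    IonSpecies,
    ParameterSet,
    PhysicalConstants,
    validate_parameters,
)
from .errors import ConfigError
from .fem import Discretization, FunctionSpace
from .geometry import GeometrySpec, Mesh, build_mesh
from .protocols import Protocol, chemical_protocol, electrical_protocol
from .solver import (
    SolverOptions,
    run_transient,
    solve_chemical_equilibrium,
)

__all__ = [
    "RunConfig",
    "load_config",
    "load_preset",
    "preset_names",
    "dump_config",
    "run_scenario",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_StrictModel):
    dimension: int = 1
    bath_extent: float | tuple[float, ...] = 1.5e-6
    gel_shape: Literal["interval", "square", "disc"] = "interval"
    gel_extent: float = 2.5e-7
    gel_center: float | tuple[float, ...] | None = None
    refinement_band: float = 2.0e-7
    base_resolution: float = 3.0e-8
    refined_resolution: float = 2.0e-9
    symmetric: bool = False

    def to_spec(self) -> GeometrySpec:
        extent = self.bath_extent
        if isinstance(extent, (int, float)):
            extent = (float(extent),) * self.dimension
        center = self.gel_center
        if center is None:
            center = tuple(e / 2.0 for e in extent)
        elif isinstance(center, (int, float)):
            center = (float(center),) * self.dimension
        return GeometrySpec(
            dimension=self.dimension,
            bath_extent=tuple(extent),
            gel_shape=self.gel_shape,
            gel_extent=self.gel_extent,
            gel_center=tuple(center),
            refinement_band=self.refinement_band,
            base_resolution=self.base_resolution,
            refined_resolution=self.refined_resolution,
            symmetric=self.symmetric,
        )


class ConstantsConfig(_StrictModel):
    faraday: float = 9.6487e4
    gas_constant: float = 8.3143
    temperature: float = 293.0
    vacuum_permittivity: float = 8.854e-12
    relative_permittivity: float = 100.0

    def to_constants(self) -> PhysicalConstants:
        return PhysicalConstants(**self.model_dump())


class SpeciesConfig(_StrictModel):
    name: str
    valence: int
    diffusivity: float = 1.0e-7
    mobility: float | None = None

    def to_species(self) -> IonSpecies:
        return IonSpecies(**self.model_dump())


class FixedChargeConfig(_StrictModel):
    concentration: float = 2.0
    valence: int = -1
    region: str = "gel"

    def to_field(self) -> FixedChargeField:
        return FixedChargeField(**self.model_dump())


class BathConfig(_StrictModel):
    # single molarity (applied to every species) or one value per species name
    molarity: float | dict[str, float] = 1.0


class ProtocolConfig(_StrictModel):
    protocol: Literal["chemical", "electrical"] = "chemical"
    applied_mV: float = 50.0
    anode_side: Literal["left", "right"] = "left"


class SolverConfig(_StrictModel):
    dt: float = 2.5e-7
    t_end: float = 5.0e-5
    order: int = 2
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

    def to_options(self) -> SolverOptions:
        d = self.model_dump()
        d.pop("order")
        return SolverOptions(**d)


class OutputConfig(_StrictModel):
    directory: str = "results"
    write_vtk: bool = False
    write_profiles: bool = True
    write_mesh: bool = False
    profile_samples: int = 400


class RunConfig(_StrictModel):
    """Complete, validated description of one simulation run."""

    name: str = "run"
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    constants: ConstantsConfig = Field(default_factory=ConstantsConfig)
    species: list[SpeciesConfig]
    fixed_charge: FixedChargeConfig = Field(default_factory=FixedChargeConfig)
    bath: BathConfig = Field(default_factory=BathConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)
    seed: int = 0

    # -- domain-object builders ---------------------------------------

    def build_geometry(self) -> GeometrySpec:
        return self.geometry.to_spec()

    def build_params(self) -> ParameterSet:
        species = tuple(s.to_species() for s in self.species)
        mol = self.bath.molarity
        if isinstance(mol, dict):
            molarity = tuple(mol[s.name] for s in species)
        else:
            molarity = (float(mol),) * len(species)
        bath = BathComposition(species=species, molarity=molarity)
        return validate_parameters(
            self.constants.to_constants(), species,
            self.fixed_charge.to_field(), bath,
        )

    def build_protocol(self, params: ParameterSet) -> Protocol:
        p = self.protocol
        if p.protocol == "chemical":
            return chemical_protocol(params.bath)
        return electrical_protocol(
            params.bath, p.applied_mV * 1e-3, polarity=f"anode_{p.anode_side}"
        )

    def build_solver_options(self) -> SolverOptions:
        return self.solver.to_options()


def _validate_dict(data: dict, source: str) -> RunConfig:
    try:
        return RunConfig.model_validate(data)
    except pydantic.ValidationError as exc:
        details = "; ".join(
            ".".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"{source}: {details}") from exc


def load_config(path: str | os.PathLike) -> RunConfig:
    """Load and validate a JSON or TOML run configuration."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ConfigError(f"config file not found: {path}")
    if path.endswith(".toml"):
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    return _validate_dict(data, path)


def dump_config(config: RunConfig) -> dict:
    """Normalized plain-dict form; dump(load(x)) is a fixpoint."""
    return config.model_dump(mode="json")


def preset_names() -> list[str]:
    files = resources.files("gelpnp.presets")
    return sorted(
        f.name[:-5] for f in files.iterdir() if f.name.endswith(".json")
    )


def load_preset(name: str) -> RunConfig:
    """Load a bundled preset configuration by name."""
    files = resources.files("gelpnp.presets")
    ref = files / f"{name}.json"
    if not ref.is_file():
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        )
    return _validate_dict(json.loads(ref.read_text()), f"preset:{name}")


# ---------------------------------------------------------------- scenario

def _gel_center_point(spec: GeometrySpec) -> np.ndarray:
    return np.array(spec.gel_center, dtype=float)


def _bath_reference_point(spec: GeometrySpec) -> np.ndarray:
    p = np.array(spec.gel_center, dtype=float)
    p[0] = 0.5 * (spec.gel_center[0] - spec.gel_extent)
    return p


def run_scenario(config: RunConfig, directory: str | os.PathLike | None = None) -> dict:
    """Mesh -> protocol -> solve -> postprocess -> export; returns the summary.

    The machine-readable summary holds the final bulk gel concentrations and
    potential jump (sampled at the gel center against a bath reference point
    halfway between the left electrode and the gel), the closed-form Donnan
    values, the steady-state time for transients, and Newton statistics.
    Identical configurations produce byte-identical summaries.
    """
    spec = config.build_geometry()
    params = config.build_params()
    protocol = config.build_protocol(params)
    options = config.build_solver_options()
    disc = Discretization(order=config.solver.order,
                          lumped_mass=config.solver.lumped_mass)
    mesh = build_mesh(spec)

    equilibrium = solve_chemical_equilibrium(params, mesh, options=options,
                                             discretization=disc)
    steady_time = None
    newton_counts: list[int] = []
    if protocol.name == "electrical":
        result = run_transient(equilibrium, params, mesh, protocol, options,
                               discretization=disc)
        final = result.states[-1]
        steady_time = result.steady_state_time
        newton_counts = result.newton_iterations
    else:
        result = None
        final = equilibrium

    space = FunctionSpace(mesh, disc)
    center = _gel_center_point(spec)
    bath_ref = _bath_reference_point(spec)
    at_center = postprocess.sample_fields(final, space, center[None, :])
    at_bath = postprocess.sample_fields(final, space, bath_ref[None, :])
    oracle = DonnanEquilibrium.solve(params.fixed_charge, params.bath,
                                     params.constants)
    summary = {
        "name": config.name,
        "scenario": protocol.name,
        "seed": config.seed,
        "gel_center": {k: float(v[0]) for k, v in at_center.items()},
        "bath_reference": {k: float(v[0]) for k, v in at_bath.items()},
        "potential_jump_V": float(at_center["potential"][0]
                                  - at_bath["potential"][0]),
        "donnan_oracle": {
            "gel_cation": oracle.gel_cation,
            "gel_anion": oracle.gel_anion,
            "potential_jump_V": oracle.potential_jump,
        },
        "steady_state_time_s": steady_time,
        "newton_iterations_total": int(sum(newton_counts)),
        "n_dofs_per_field": space.ndof,
        "n_time_steps": len(newton_counts),
    }
    if directory is not None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        if config.output.write_profiles:
            profile = postprocess.extract_line_profile(
                final, mesh, axis="x",
                n_samples=config.output.profile_samples, space=space,
            )
            postprocess.export_profile_csv(
                profile, os.path.join(directory, "profile_x.csv")
            )
        if config.output.write_vtk:
            target = result if result is not None else final
            postprocess.export_fields(target, mesh, directory)
        if config.output.write_mesh:
            from . import mshio

            mshio.write_msh(mesh, os.path.join(directory, "mesh.msh"))
    return summary
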