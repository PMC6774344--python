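"""Stimulation scenarios translated into boundary conditions and initial states.

Two protocols are supported:

* **chemical** - the gel equilibrates with a well-stirred bath: ion
  concentrations are fixed at the bath values and the potential at 0 V on
  both electrode boundaries, top/bottom insulated.  The initial state is
  uniform at bath values.
* **electrical** - a constant voltage is applied across the bath: the anode
  electrode is held at the applied potential, the cathode at 0 V, and the
  electrode-side concentrations stay pinned at bath values (well-stirred
  bath).  The initial state must be the chemical-equilibrium solution.

Electrodes are ideal Dirichlet surfaces: the experimental practice of
isolating the sample from electrolysis products (agar salt bridges) is
represented by the absence of any electrode reaction in the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .core import BathComposition
from .errors import OptionError, ValidationError
from .geometry import Mesh

__all__ = [
    "BoundaryConditions",
    "Protocol",
    "chemical_protocol",
    "electrical_protocol",
]

_ELECTRODES = ("electrode_left", "electrode_right")


@dataclass(frozen=True)
class BoundaryConditions:
    """Per-tag boundary data for the potential and each species.

    ``potential[tag]`` is a Dirichlet value in volts or ``None`` for an
    insulated (zero normal flux) boundary; ``concentration[tag][name]``
    likewise in mol m^-3 or ``None`` for zero flux.
    """

    potential: Mapping[str, float | None]
    concentration: Mapping[str, Mapping[str, float | None]]

    def validate(self, mesh: Mesh, require_potential_dirichlet: bool = False) -> None:
        """Check the BC covers every boundary tag of ``mesh`` exactly once."""
        import numpy as np

        tags = set(np.unique(mesh.boundary_tags).tolist())
        missing = tags - set(self.potential)
        if missing:
            raise ValidationError("bc_coverage",
                                  f"no potential condition for tags {sorted(missing)}")
        missing = tags - set(self.concentration)
        if missing:
            raise ValidationError("bc_coverage",
                                  f"no concentration condition for tags {sorted(missing)}")
        if require_potential_dirichlet and not any(
            v is not None for t, v in self.potential.items() if t in tags
        ):
            raise ValidationError(
                "bc_wellposedness",
                "electrical scenarios need at least one potential Dirichlet datum",
            )

    def has_potential_dirichlet(self) -> bool:
        return any(v is not None for v in self.potential.values())


@dataclass(frozen=True)
class Protocol:
    """Boundary conditions plus the initial-state requirement of a scenario.

    ``initial_uniform`` maps species name -> uniform initial concentration
    (potential starts at 0 V) when the scenario starts from a uniform state;
    ``initial_requirement`` is 'uniform' or 'chemical_equilibrium'.
    """

    name: str
    boundary_conditions: BoundaryConditions
    initial_uniform: Mapping[str, float] = field(default_factory=dict)
    initial_requirement: str = "uniform"


def _bath_concentration_bc(bath: BathComposition) -> dict[str, dict[str, float | None]]:
    on_electrode = {s.name: c for s, c in zip(bath.species, bath.molarity)}
    return {
        "electrode_left": dict(on_electrode),
        "electrode_right": dict(on_electrode),
        "insulated": {s.name: None for s in bath.species},
    }


def chemical_protocol(bath: BathComposition) -> Protocol:
    """Zero applied field; concentrations pinned to bath values at electrodes."""
    bc = BoundaryConditions(
        potential={"electrode_left": 0.0, "electrode_right": 0.0,
                   "insulated": None},
        concentration=_bath_concentration_bc(bath),
    )
    return Protocol(
        name="chemical",
        boundary_conditions=bc,
        initial_uniform={s.name: c for s, c in zip(bath.species, bath.molarity)},
        initial_requirement="uniform",
    )


def electrical_protocol(
    bath: BathComposition,
    applied_voltage: float,
    polarity: str = "anode_left",
) -> Protocol:
    """Constant-voltage stimulation: anode at ``applied_voltage``, cathode at 0 V.

    ``polarity`` is ``'anode_left'`` or ``'anode_right'``.  The returned
    protocol declares ``initial_requirement='chemical_equilibrium'``: the
    chemical-stimulation steady state supplies the initial condition.
    """
    if not math.isfinite(applied_voltage):
        raise OptionError("applied_voltage must be finite")
    if polarity == "anode_left":
        pot = {"electrode_left": float(applied_voltage),
               "electrode_right": 0.0, "insulated": None}
    elif polarity == "anode_right":
        pot = {"electrode_left": 0.0,
               "electrode_right": float(applied_voltage), "insulated": None}
    else:
        raise OptionError(
            f"unknown polarity {polarity!r}; use 'anode_left' or 'anode_right'"
        )
    bc = BoundaryConditions(
        potential=pot,
        concentration=_bath_concentration_bc(bath),
    )
    return Protocol(
        name="electrical",
        boundary_conditions=bc,
        initial_uniform={s.name: c for s, c in zip(bath.species, bath.molarity)},
        initial_requirement="chemical_equilibrium",
    )
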