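"""Physical constants, species/material parameters, and the Donnan equilibrium.

The model describes a polyelectrolyte hydrogel carrying bound (immobile) ionic
groups of concentration ``c_f`` and valence ``z_f``, immersed in a binary
monovalent electrolyte bath (NaCl).  At chemical equilibrium the mobile ions
partition between gel and bath according to the ideal Donnan equilibrium:
electroneutrality inside the gel,

    z+ c_gel+ + z- c_gel- + z_f c_f = 0,

together with the ideal Donnan product c_gel+ * c_gel- = c_sol^2, and a
potential jump (Donnan potential) across the gel-solution interface,

    dphi = (R T / (z_k F)) ln(c_sol,k / c_gel,k),

identical for either mobile species.  These closed forms are the analytic
oracle against which the finite-element Poisson-Nernst-Planck solver is
validated.

Units are SI throughout: mol m^-3 for concentrations (1 mM == 1 mol m^-3),
volts, meters, seconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

from .errors import (
    MobilityInconsistencyWarning,
    ParameterError,
    UnsupportedConfigurationError,
    ValidationError,
)

__all__ = [
    "PhysicalConstants",
    "IonSpecies",
    "FixedChargeField",
    "BathComposition",
    "DonnanEquilibrium",
    "ParameterSet",
    "nernst_einstein_mobility",
    "donnan_concentrations",
    "donnan_potential",
    "validate_parameters",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants and ambient conditions.

    Defaults reproduce the validation scenario of the underlying hydrogel
    transport model: F = 9.6487e4 C/mol, R = 8.3143 J/(mol K), T = 293 K,
    eps0 = 8.854e-12 A s/(V m), eps_r = 100.  The thermal voltage
    R*T/F evaluates to ~25.25 mV at these defaults.
    """

    faraday: float = 9.6487e4
    gas_constant: float = 8.3143
    temperature: float = 293.0
    vacuum_permittivity: float = 8.854e-12
    relative_permittivity: float = 100.0

    def __post_init__(self):
        for name in (
            "faraday",
            "gas_constant",
            "temperature",
            "vacuum_permittivity",
            "relative_permittivity",
        ):
            if not getattr(self, name) > 0.0:
                raise ParameterError(f"{name} must be strictly positive")

    @property
    def thermal_voltage(self) -> float:
        """R*T/F in volts (~0.02525 V at defaults)."""
        return self.gas_constant * self.temperature / self.faraday

    @property
    def permittivity(self) -> float:
        """Absolute permittivity eps_r * eps0 in A s / (V m)."""
        return self.relative_permittivity * self.vacuum_permittivity


def nernst_einstein_mobility(diffusivity: float, constants: PhysicalConstants) -> float:
    """Ionic mobility mu = D*F/(R*T) in m^2 s^-1 V^-1.

    With the default constants and D = 1.0e-7 m^2/s this evaluates to
    3.9607e-6 m^2 s^-1 V^-1.
    """
    if diffusivity < 0.0:
        raise ParameterError("diffusivity must be non-negative")
    return diffusivity * constants.faraday / (
        constants.gas_constant * constants.temperature
    )


@dataclass(frozen=True)
class IonSpecies:
    """One mobile ionic species: valence z_k and diffusivity D_k.

    ``mobility`` may be stored explicitly; when absent it is derived from the
    Nernst-Einstein relation at the ambient constants.
    """

    name: str
    valence: int
    diffusivity: float
    mobility: float | None = None

    def __post_init__(self):
        if self.valence == 0 or abs(self.valence) > 3:
            raise ParameterError(
                f"valence must be a nonzero integer in [-3, 3], got {self.valence}"
            )
        if not self.diffusivity > 0.0:
            raise ParameterError("diffusivity must be strictly positive")
        if self.mobility is not None and not self.mobility > 0.0:
            raise ParameterError("stored mobility must be strictly positive")

    def mobility_at(self, constants: PhysicalConstants) -> float:
        """Stored mobility if present, else Nernst-Einstein D*F/(R*T)."""
        if self.mobility is not None:
            return self.mobility
        return nernst_einstein_mobility(self.diffusivity, constants)


@dataclass(frozen=True)
class FixedChargeField:
    """Bound ionic charge of the gel network: magnitude c_f >= 0, valence z_f.

    The contribution to the charge density is z_f*c_f on the tagged gel
    region and zero elsewhere.
    """

    concentration: float
    valence: int = -1
    region: str = "gel"

    def __post_init__(self):
        if self.concentration < 0.0:
            raise ParameterError("fixed-charge concentration must be >= 0")
        if self.valence == 0:
            raise ParameterError("fixed-charge valence must be nonzero")


@dataclass(frozen=True)
class BathComposition:
    """Mobile species and their bath (electrode-boundary) concentrations.

    ``molarity`` is ordered like ``species``; the bath must be electroneutral.
    """

    species: tuple[IonSpecies, ...]
    molarity: tuple[float, ...]

    def __post_init__(self):
        if len(self.species) != len(self.molarity):
            raise ParameterError("one molarity per species required")
        if any(c < 0.0 for c in self.molarity):
            raise ParameterError("bath molarities must be >= 0")

    @classmethod
    def nacl(cls, concentration: float, diffusivity: float = 1.0e-7) -> "BathComposition":
        """Symmetric binary monovalent electrolyte at the given concentration."""
        return cls(
            species=(
                IonSpecies("Na+", +1, diffusivity),
                IonSpecies("Cl-", -1, diffusivity),
            ),
            molarity=(concentration, concentration),
        )

    @property
    def charge_imbalance(self) -> float:
        return sum(s.valence * c for s, c in zip(self.species, self.molarity))

    def concentration_of(self, name: str) -> float:
        for s, c in zip(self.species, self.molarity):
            if s.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class DonnanEquilibrium:
    """Closed-form equilibrium gel concentrations and the Donnan potential.

    Satisfies the ideal Donnan product gel_cation*gel_anion = c_sol^2 and gel
    electroneutrality; ``potential_jump`` is gel minus bath, negative for an
    anionic gel.
    """

    gel_cation: float
    gel_anion: float
    potential_jump: float

    @classmethod
    def solve(
        cls,
        fixed_charge: FixedChargeField,
        bath: BathComposition,
        constants: PhysicalConstants | None = None,
    ) -> "DonnanEquilibrium":
        constants = constants or PhysicalConstants()
        cation, anion = donnan_concentrations(fixed_charge, bath)
        eq = cls(gel_cation=cation, gel_anion=anion, potential_jump=0.0)
        dphi = donnan_potential(eq, bath, constants)
        return replace(eq, potential_jump=dphi)


def _monovalent_pair(bath: BathComposition) -> tuple[IonSpecies, IonSpecies, float]:
    """Return (cation, anion, c_sol) for a symmetric monovalent binary bath."""
    if len(bath.species) != 2:
        raise UnsupportedConfigurationError(
            "Donnan closed form supports exactly two mobile species"
        )
    zs = sorted(s.valence for s in bath.species)
    if zs != [-1, 1]:
        raise UnsupportedConfigurationError(
            "Donnan closed form supports a monovalent binary electrolyte (z = +1, -1)"
        )
    if abs(bath.charge_imbalance) > 1e-12 * (1.0 + max(bath.molarity)):
        raise ValidationError("bath_electroneutrality", "sum(z_k c_sol,k) != 0")
    cation = next(s for s in bath.species if s.valence == +1)
    anion = next(s for s in bath.species if s.valence == -1)
    c_sol = bath.concentration_of(cation.name)
    return cation, anion, c_sol


def donnan_concentrations(
    fixed_charge: FixedChargeField, bath: BathComposition
) -> tuple[float, float]:
    """Equilibrium (gel_cation, gel_anion) for a monovalent binary electrolyte.

    Unique positive root pair of gel electroneutrality
    c+ - c- + z_f c_f = 0 and the ideal Donnan product c+ * c- = c_sol^2:

        c- = (z_f c_f + sqrt((z_f c_f)^2 + 4 c_sol^2)) / 2,   c+ = c- - z_f c_f.

    For c_f = 2 mol/m^3 (z_f = -1), c_sol = 1 mol/m^3 this gives
    (2.4142, 0.4142) mol/m^3.
    """
    if abs(fixed_charge.valence) != 1:
        raise UnsupportedConfigurationError(
            "Donnan closed form supports |z_f| = 1 (generalization is a non-goal)"
        )
    _, _, c_sol = _monovalent_pair(bath)
    if not c_sol > 0.0:
        raise ParameterError("bath concentration must be strictly positive")
    s = fixed_charge.valence * fixed_charge.concentration
    root = math.sqrt(s * s + 4.0 * c_sol * c_sol)
    # evaluate the larger concentration by the non-cancelling branch and the
    # smaller one through the Donnan product (stable for c_f >> c_sol)
    if s <= 0.0:  # anionic gel: cation is the counter-ion, the larger value
        cation = 0.5 * (root - s)
        anion = c_sol * c_sol / cation
    else:
        anion = 0.5 * (root + s)
        cation = c_sol * c_sol / anion
    return cation, anion


def donnan_potential(
    equilibrium: DonnanEquilibrium,
    bath: BathComposition,
    constants: PhysicalConstants,
) -> float:
    """Donnan potential jump (gel minus bath) in volts.

    dphi = (R T / (z_k F)) * ln(c_sol,k / c_gel,k), evaluated with both the
    cation and the anion; the two must agree to 1e-12 relative (they do
    whenever the concentrations satisfy the Donnan product).  Negative for an
    anionic gel.
    """
    cation, anion, c_sol = _monovalent_pair(bath)
    for label, c in (("gel_cation", equilibrium.gel_cation),
                     ("gel_anion", equilibrium.gel_anion)):
        if not c > 0.0:
            raise ParameterError(f"{label} must be strictly positive")
    if not c_sol > 0.0:
        raise ParameterError("bath concentration must be strictly positive")
    vt = constants.thermal_voltage
    via_cation = vt / cation.valence * math.log(c_sol / equilibrium.gel_cation)
    via_anion = vt / anion.valence * math.log(c_sol / equilibrium.gel_anion)
    scale = max(abs(via_cation), abs(via_anion), 1e-300)
    if abs(via_cation - via_anion) > 1e-9 * scale:
        warnings.warn(
            "cation- and anion-based Donnan potentials disagree; "
            "concentrations do not satisfy the ideal Donnan product",
            stacklevel=2,
        )
    return via_cation


@dataclass(frozen=True)
class ParameterSet:
    """A validated bundle of all physical parameters for one simulation."""

    constants: PhysicalConstants
    cation: IonSpecies
    anion: IonSpecies
    fixed_charge: FixedChargeField
    bath: BathComposition

    @property
    def species(self) -> tuple[IonSpecies, IonSpecies]:
        return (self.cation, self.anion)

    def bath_concentration(self, species: IonSpecies) -> float:
        return self.bath.concentration_of(species.name)


def validate_parameters(
    constants: PhysicalConstants,
    species: Sequence[IonSpecies],
    fixed_charge: FixedChargeField,
    bath: BathComposition,
) -> ParameterSet:
    """Check all type invariants and return a validated :class:`ParameterSet`.

    Raises :class:`~gelpnp.errors.ValidationError` (named per invariant) on
    violations; emits :class:`~gelpnp.errors.MobilityInconsistencyWarning`
    (without failing) when a stored mobility disagrees with the
    Nernst-Einstein value by more than 1e-4 relative.
    """
    species = tuple(species)
    if tuple(bath.species) != species:
        raise ValidationError("species_bath_mismatch",
                              "bath.species must equal the supplied species list")
    if len(species) != 2:
        raise ValidationError("species_count",
                              "exactly two mobile species are supported")
    zs = sorted(s.valence for s in species)
    if zs != [-1, 1]:
        raise ValidationError("species_valences",
                              "species valences must be +1 and -1")
    imbalance = bath.charge_imbalance
    if abs(imbalance) > 1e-12 * (1.0 + max(bath.molarity)):
        raise ValidationError(
            "bath_electroneutrality",
            f"sum(z_k c_sol,k) = {imbalance:g} != 0",
        )
    if not all(c > 0.0 for c in bath.molarity):
        raise ValidationError("bath_molarity", "bath molarities must be > 0")
    for s in species:
        if s.mobility is not None:
            mu_ne = nernst_einstein_mobility(s.diffusivity, constants)
            if abs(s.mobility - mu_ne) > 1e-4 * mu_ne:
                warnings.warn(
                    MobilityInconsistencyWarning(
                        f"species {s.name!r}: stored mobility {s.mobility:g} "
                        f"differs from Nernst-Einstein value {mu_ne:g} "
                        "by more than 1e-4 relative"
                    ),
                    stacklevel=2,
                )
    cation = next(s for s in species if s.valence > 0)
    anion = next(s for s in species if s.valence < 0)
    return ParameterSet(
        constants=constants,
        cation=cation,
        anion=anion,
        fixed_charge=fixed_charge,
        bath=bath,
    )
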